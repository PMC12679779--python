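"""Readers and writers for genotype and phenotype files.

Genotypes travel either as a CSV dosage matrix (lines x markers, header row
of marker IDs, first column of line IDs, missing = NA) or as a minimal
biallelic VCF (GT 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing).
Phenotypes use a long-format CSV with columns
``genotype,year,block,regime,trait,value``; wide per-trait tables with the
first four columns plus one column per trait are melted automatically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from wheatgs.genotypes import GenotypeMatrix
from wheatgs.phenotypes import REQUIRED_COLUMNS, PhenotypeTable

__all__ = [
    "read_genotypes", "write_genotype_csv", "read_genotype_csv",
    "write_vcf", "read_vcf", "read_phenotypes", "write_phenotypes",
    "write_qc_report",
]

_GT_TO_DOSE = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 2.0}


# -- CSV dosage dialect -----------------------------------------------------

def write_genotype_csv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosages, index=g.line_ids, columns=g.marker_ids)
    df.index.name = "line"
    df.to_csv(path, na_rep="NA", float_format="%.0f")


def read_genotype_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        raise ValueError("duplicate line IDs in genotype CSV")
    if df.columns.duplicated().any():
        raise ValueError("duplicate marker IDs in genotype CSV")
    return GenotypeMatrix(list(df.index.astype(str)),
                          list(df.columns.astype(str)),
                          df.to_numpy(dtype=float))


# -- VCF --------------------------------------------------------------------

def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal diploid VCF (one synthetic contig)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(l) for l in g.line_ids) + "\n")
        for j, marker in enumerate(g.marker_ids):
            calls = [code.get(d, "./.") if not np.isnan(d) else "./."
                     for d in g.dosages[:, j]]
            fh.write(f"1\t{j + 1}\t{marker}\tA\tB\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF into a dosage matrix.

    Multi-allelic records are rejected with an error naming the site;
    duplicate line or marker IDs are errors.
    """
    with pysam.VariantFile(str(path)) as vcf:
        line_ids = list(vcf.header.samples)
        if len(set(line_ids)) != len(line_ids):
            raise ValueError("duplicate line IDs in VCF header")
        marker_ids, rows = [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos} "
                    f"({rec.id or 'unnamed'}); only biallelic sites are supported"
                )
            marker_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            row = []
            for sample in line_ids:
                gt = rec.samples[sample]["GT"]
                row.append(_GT_TO_DOSE.get(tuple(gt) if gt else None, np.nan)
                           if gt and None not in gt else np.nan)
            rows.append(row)
    if len(set(marker_ids)) != len(marker_ids):
        raise ValueError("duplicate marker IDs in VCF")
    return GenotypeMatrix(line_ids, marker_ids,
                          np.asarray(rows, dtype=float).T)


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes, inferring the format from the extension if not given."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "csv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "csv":
        return read_genotype_csv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# -- phenotypes -------------------------------------------------------------

def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path)
    if not set(REQUIRED_COLUMNS) <= set(df.columns):
        id_cols = ["genotype", "year", "block", "regime"]
        if set(id_cols) <= set(df.columns):
            value_cols = [c for c in df.columns if c not in id_cols]
            if not value_cols:
                raise ValueError("wide phenotype table has no trait columns")
            df = df.melt(id_vars=id_cols, value_vars=value_cols,
                         var_name="trait", value_name="value")
        else:
            missing = sorted(set(REQUIRED_COLUMNS) - set(df.columns))
            raise ValueError(f"phenotype file missing required columns: {missing}")
    return PhenotypeTable(df)


def write_phenotypes(p: PhenotypeTable, path) -> None:
    p.records.to_csv(path, index=False)


def write_qc_report(report, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
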