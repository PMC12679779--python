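"""Plot-level phenotype records from multi-year, blocked trials.

The canonical representation is a long-format table with one row per plot
observation: ``genotype, year, block, regime, trait, value``.  Line means
(per genotype within a regime, averaged over years and blocks) are the unit
of analysis for genomic prediction; the combined-water-regime (CWR) values
are per-genotype means of the WS and WW line means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PhenotypeTable", "REQUIRED_COLUMNS", "CWR"]

REQUIRED_COLUMNS = ("genotype", "year", "block", "regime", "trait", "value")

#: pseudo-regime name for per-line means pooled over both water regimes
CWR = "CWR"


@dataclass
class PhenotypeTable:
    """Long-format plot-level phenotype records."""

    records: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.records)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing required columns: {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["value"] = pd.to_numeric(df["value"])
        key = ["genotype", "year", "block", "regime", "trait"]
        dup = df.duplicated(subset=key)
        if dup.any():
            rows = df.loc[dup, key].head(5).to_dict("records")
            raise ValueError(f"duplicate plot records, e.g. {rows}")
        self.records = df.reset_index(drop=True)

    # -- vocabulary -----------------------------------------------------

    @property
    def traits(self) -> list:
        return sorted(self.records["trait"].unique())

    @property
    def regimes(self) -> list:
        return sorted(self.records["regime"].unique())

    @property
    def genotypes(self) -> list:
        return sorted(self.records["genotype"].unique())

    def subset(self, trait=None, regime=None) -> "PhenotypeTable":
        df = self.records
        if trait is not None:
            df = df[df["trait"] == trait]
        if regime is not None:
            df = df[df["regime"] == regime]
        if df.empty:
            raise ValueError(f"no records for trait={trait!r} regime={regime!r}")
        return PhenotypeTable(df)

    # -- line means ------------------------------------------------------

    def line_means(self, trait: str, regime: str) -> pd.Series:
        """Per-genotype trait means within a regime (over years and blocks).

        ``regime="CWR"`` returns the per-genotype mean of the WS and WW
        line means (each regime weighted equally regardless of plot counts).
        """
        if regime == CWR:
            per_regime = [self.line_means(trait, r) for r in self.regimes]
            out = pd.concat(per_regime, axis=1).mean(axis=1)
            out.name = trait
            return out
        df = self.records
        sel = (df["trait"] == trait) & (df["regime"] == regime)
        if not sel.any():
            raise ValueError(f"no records for trait={trait!r} regime={regime!r}")
        out = df.loc[sel].groupby("genotype")["value"].mean().sort_index()
        out.name = trait
        return out

    def line_mean_frame(self, regime: str) -> pd.DataFrame:
        """Genotype x trait matrix of line means for one regime (or CWR)."""
        cols = {t: self.line_means(t, regime) for t in self.traits}
        return pd.DataFrame(cols)

    def check_against_genotypes(self, line_ids) -> "PhenotypeTable":
        """Drop records whose genotype is absent from ``line_ids``; report them.

        Returns the filtered table; the dropped ids are stored on the result
        as ``.unmatched`` for logging.
        """
        known = set(line_ids)
        present = set(self.records["genotype"])
        unmatched = sorted(present - known)
        df = self.records[self.records["genotype"].isin(known)]
        if df.empty:
            raise ValueError("no phenotype record matches any genotyped line")
        out = PhenotypeTable(df)
        out.unmatched = unmatched
        return out

    def __len__(self) -> int:
        return len(self.records)
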