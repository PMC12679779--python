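"""Marker quality control of the simulated panel.

Masks heterozygous calls, drops markers with > 30% missing data or
MAF < 5%, and kNN-imputes (K = 5) the remainder.  Writes the cleaned
dosage matrix and the QC report.
"""

import json
from pathlib import Path

from wheatgs import io
from wheatgs.genoqc import QCConfig, run_qc

DATA = Path("results/data")


def main():
    geno = io.read_genotypes(DATA / "genotypes.csv")
    clean, report = run_qc(geno, QCConfig(maf_threshold=0.05, max_missing=0.30,
                                          knn_k=5))
    io.write_genotype_csv(clean, DATA / "genotypes_clean.csv")
    io.write_qc_report(report, DATA / "qc_report.json")
    print(json.dumps(report.as_dict(), indent=2))
    print(f"retained {report.n_output_markers}/{report.n_input_markers} markers "
          f"({100 * report.n_output_markers / report.n_input_markers:.1f}%), "
          f"imputed {report.n_imputed_cells} cells")


if __name__ == "__main__":
    main()
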