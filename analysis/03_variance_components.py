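"""Variance components, heritability and trait correlations.

Fits the plot-level REML mixed model per trait x regime (WS, WW and the
combined CWR), tabulates GV/PV/EV, the coefficients of variation and H2,
and computes within- and cross-regime Pearson correlations of line means.
"""

from pathlib import Path

from wheatgs import io
from wheatgs.quantgen import trait_correlations, variance_table

DATA = Path("results/data")
OUT = Path("results")


def main():
    pheno = io.read_phenotypes(DATA / "phenotypes.csv")
    tab = variance_table(pheno)
    tab.to_csv(OUT / "variance_components.csv", index=False)
    print(tab.round(3).to_string(index=False))

    corr = trait_correlations(pheno)
    for key in ("WS", "WW", "cross"):
        corr[key].to_csv(OUT / f"correlations_{key}.csv")
    print("\ncross-regime correlations of line means (attenuated by H2):")
    print(corr["cross"].round(2).to_string())


if __name__ == "__main__":
    main()
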