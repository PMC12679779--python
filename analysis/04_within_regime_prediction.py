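"""Within-regime genomic prediction under KFCV and LOOCV.

Evaluates the ten models on the simulated panel.  Problem sizes are scaled
for a desk run: repeated 80:20 CV uses 15 iterations (the fast models) and
the five Gibbs-sampled Bayesian models are evaluated on the water-stressed
regime with 10 iterations and 400/150 chains; LOOCV covers the four fast
models on the water-stressed regime with fixed hyperparameters.  Writes the
long-format results plus per-regime grids of r_MP, r_MG and RMSE.
"""

from pathlib import Path

from wheatgs import io
from wheatgs.evalharness import EvalScheme, run_kfcv, run_loocv, summarize
from wheatgs.gsmodels import make_model
from wheatgs.phenotypes import CWR
from wheatgs.quantgen import fit_mixed_model, heritability
from wheatgs.study import seed_for

DATA = Path("results/data")
OUT = Path("results")
SEED = 2024

BAYES = ("bayes_a", "bayes_b", "bayes_c", "brr", "bayes_lasso")
FAST = ("rrblup", "rkhs", "rf", "svm", "xgb")
CHAIN = {"n_iter": 400, "burn_in": 150, "thin": 1}
GRIDS = {
    "rf": {"max_depth": [40], "max_features": ["sqrt"], "n_estimators": [100]},
    "xgb": {"max_depth": [4], "learning_rate": [0.1], "n_estimators": [150]},
    "svm": {"svr__C": [1.0], "svr__gamma": ["scale"]},
}


def factory(name, seed):
    params = dict(CHAIN) if name in BAYES else (
        {"grid": GRIDS[name]} if name in GRIDS else {})
    return lambda: make_model(name, seed=seed, **params)


def main():
    geno = io.read_genotypes(DATA / "genotypes_clean.csv")
    pheno = io.read_phenotypes(DATA / "phenotypes.csv")
    X, lines = geno.dosages, geno.line_ids

    results = []
    for trait in pheno.traits:
        for regime in ("WS", "WW", CWR):
            h2 = heritability(fit_mixed_model(pheno, trait, regime))
            y = pheno.line_means(trait, regime).reindex(lines).to_numpy()
            models = FAST + (BAYES if regime == "WS" else ())
            for name in models:
                seed = seed_for(SEED, trait, name, "kfcv", regime)
                n_iter = 10 if name in BAYES else 15
                res = run_kfcv(X, y, factory(name, seed),
                               EvalScheme(kind="kfcv", n_iterations=n_iter,
                                          seed=seed),
                               h2=h2, trait=trait, regime=regime,
                               model_name=name)
                results.append(res)
                print(f"kfcv  {trait:4s} {regime:3s} {name:12s} "
                      f"r_MP={res.r_mp:+.2f}+-{res.r_mp_sd:.2f} "
                      f"r_MG={res.r_mg:+.2f}", flush=True)
            if regime == "WS":
                for name in ("rrblup", "rf", "svm", "xgb"):
                    seed = seed_for(SEED, trait, name, "loocv", regime)
                    res = run_loocv(X, y, factory(name, seed), h2=h2,
                                    trait=trait, regime=regime,
                                    model_name=name)
                    results.append(res)
                    print(f"loocv {trait:4s} {regime:3s} {name:12s} "
                          f"r_MP={res.r_mp:+.2f} r_MG={res.r_mg:+.2f}",
                          flush=True)

    tables = summarize(results)
    tables["long"].to_csv(OUT / "within_regime_results.csv", index=False)
    for (scheme, regime, metric), wide in tables["wide"].items():
        wide.to_csv(OUT / f"table_{scheme}_{regime}_{metric}.csv")
    tables["means"].to_csv(OUT / "within_regime_model_means.csv", index=False)
    print("\nper-regime model means (printed-precision arithmetic):")
    m = tables["means"]
    print(m[m.metric == "r_MG"].round(2).to_string(index=False))


if __name__ == "__main__":
    main()
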