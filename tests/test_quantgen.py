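"""Mixed-model variance components, H2, CV coefficients and correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wheatgs.phenotypes import PhenotypeTable
from wheatgs.quantgen import (VarianceComponents, anova_components,
                              cv_coefficients, fit_mixed_model, heritability,
                              trait_correlations, trait_summary, _reml_neg2ll,
                              _one_hot)
from wheatgs.simdata import SimConfig, simulate_genotypes, simulate_trials


def balanced_table(values, genos, years=(2021, 2022), blocks=(1, 2),
                   regime="WS", trait="t"):
    rows = []
    it = iter(values)
    for g, y, b in itertools.product(genos, years, blocks):
        rows.append({"genotype": g, "year": y, "block": b, "regime": regime,
                     "trait": trait, "value": next(it)})
    return PhenotypeTable(pd.DataFrame(rows))


class TestHeritability:
    def test_pure_genetic_variance_gives_one(self):
        v = VarianceComponents(1.0, 0.0, 0.0, 0.0, 0.0, 2, 2)
        assert heritability(v) == 1.0

    def test_forced_arithmetic_one_third(self):
        v = VarianceComponents(1.0, 0.0, 2.0, 0.0, 4.0, 2, 2)
        assert heritability(v) == pytest.approx(1.0 / 3.0)

    def test_all_zero_components_undefined(self):
        v = VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.0, 2, 2)
        with pytest.raises(ValueError):
            heritability(v)

    def test_scale_invariance(self):
        v1 = VarianceComponents(1.3, 0.5, 0.7, 0.2, 2.1, 2, 2)
        c = 7.3
        v2 = VarianceComponents(1.3 * c, 0.5 * c, 0.7 * c, 0.2 * c, 2.1 * c, 2, 2)
        assert heritability(v1) == pytest.approx(heritability(v2))


class TestCvCoefficients:
    def test_no_environmental_variance(self):
        v = VarianceComponents(1.0, 0.0, 0.0, 0.0, 0.0, 2, 2)
        gcv, pcv, ecv = cv_coefficients(v, 10.0)
        assert gcv == pcv == pytest.approx(10.0)
        assert ecv == 0.0

    def test_direct_arithmetic(self):
        v = VarianceComponents(1.0, 0.0, 0.0, 0.0, 1.0, 1, 1)
        gcv, pcv, ecv = cv_coefficients(v, 10.0)
        assert gcv == pytest.approx(10.0)
        assert ecv == pytest.approx(10.0)
        assert pcv == pytest.approx(100 * np.sqrt(2.0) / 10.0)

    def test_pcv_at_least_gcv_for_random_components(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = rng.random(5)
            v = VarianceComponents(*s, 2, 2)
            gcv, pcv, _ = cv_coefficients(v, 5.0)
            assert pcv >= gcv

    def test_zero_mean_rejected(self):
        v = VarianceComponents(1.0, 0.0, 0.0, 0.0, 0.0, 2, 2)
        with pytest.raises(ValueError):
            cv_coefficients(v, 0.0)


class TestFitMixedModel:
    def test_zero_residual_limit(self):
        # every genotype's plots identical -> sigma2_e = 0,
        # sigma2_g = between-genotype variance
        genos = [f"G{i}" for i in range(12)]
        means = np.arange(12, dtype=float)
        values = np.repeat(means, 4)  # 2 years x 2 blocks each
        p = balanced_table(values, genos)
        v = fit_mixed_model(p, "t", "WS")
        assert v.sigma2_e < 1e-4 * means.var()
        assert v.sigma2_gy < 1e-4 * means.var()
        total = v.sigma2_g
        assert total == pytest.approx(means.var(ddof=1), rel=0.15)

    def test_reml_matches_brute_force_grid(self):
        """REML optimum equals a direct grid maximization of the restricted
        likelihood on a 10-genotype fixture (g + e model only)."""
        rng = np.random.default_rng(42)
        genos = [f"G{i}" for i in range(10)]
        g_eff = rng.normal(0, 1.0, 10)
        values = []
        for gi in range(10):
            for _ in range(4):
                values.append(5.0 + g_eff[gi] + rng.normal(0, 0.8))
        p = balanced_table(values, genos)
        df = p.records
        y = df["value"].to_numpy()
        scale = y.var()
        yn = y / np.sqrt(scale)
        Zg = _one_hot(df["genotype"])
        Zy = _one_hot(df["year"])
        Zgy = _one_hot(df["genotype"].astype(str) + "_" + df["year"].astype(str))
        Zb = _one_hot(df["year"].astype(str) + "_" + df["block"].astype(str))
        terms = [Z @ Z.T for Z in (Zg, Zy, Zgy, Zb)]

        v = fit_mixed_model(p, "t", "WS")
        theta_hat = np.array([v.sigma2_g, v.sigma2_y, v.sigma2_gy, v.sigma2_b,
                              v.sigma2_e]) / scale
        base = _reml_neg2ll(theta_hat, terms, yn)
        # the fitted point beats every grid candidate
        grid = np.array([0.0, 0.05, 0.2, 0.5, 1.0, 2.0])
        best_grid = min(
            _reml_neg2ll(np.array(t), terms, yn)
            for t in itertools.product(grid, repeat=5) if sum(t) > 0
        )
        assert base <= best_grid + 1e-6

    def test_agrees_with_anova_on_balanced_simulation(self):
        cfg = SimConfig(n_lines=80, n_markers=200, missing_rate=0.0,
                        het_rate=0.0, target_h2=0.5, seed=31)
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_trials(cfg, geno.truth)
        reml = fit_mixed_model(pheno, "trait", "WS")
        mom = anova_components(pheno, "trait", "WS")
        if all(getattr(mom, k) > 1e-6 for k in
               ("sigma2_g", "sigma2_gy", "sigma2_e")):
            assert heritability(reml) == pytest.approx(heritability(mom), abs=0.02)
            assert reml.sigma2_g == pytest.approx(mom.sigma2_g, rel=0.1)
            assert reml.sigma2_e == pytest.approx(mom.sigma2_e, rel=0.1)

    def test_single_year_degrades_gracefully(self):
        genos = [f"G{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        rows = [{"genotype": g, "year": 2021, "block": b, "regime": "WS",
                 "trait": "t", "value": rng.normal()}
                for g in genos for b in (1, 2)]
        with pytest.warns(UserWarning, match="single-year"):
            v = fit_mixed_model(PhenotypeTable(pd.DataFrame(rows)), "t", "WS")
        assert v.single_year
        assert v.sigma2_y == 0.0 and v.sigma2_gy == 0.0

    def test_h2_invariant_to_trait_rescaling(self, clean_sim):
        _, _, pheno, _ = clean_sim
        v1 = fit_mixed_model(pheno, "trait", "WS")
        scaled = PhenotypeTable(pheno.records.assign(value=pheno.records.value * 3.7))
        v2 = fit_mixed_model(scaled, "trait", "WS")
        assert heritability(v1) == pytest.approx(heritability(v2), abs=1e-3)


class TestTraitCorrelations:
    def test_self_correlation_is_one_and_cross_recovers_regime_cor(self):
        cfg = SimConfig(n_lines=150, n_markers=400, missing_rate=0.0,
                        het_rate=0.0, regime_cor=0.84, target_h2=0.69, seed=32)
        geno = simulate_genotypes(cfg)
        pheno, truth = simulate_trials(cfg, geno.truth)
        corr = trait_correlations(pheno)
        assert corr["WS"].loc["trait", "trait"] == pytest.approx(1.0)
        # the configured correlation is recovered on the true genetic values
        r_tbv = truth.true_breeding_values.corr().loc["WS", "WW"]
        se = 1.0 / np.sqrt(cfg.n_lines - 3)
        assert abs(np.arctanh(r_tbv) - np.arctanh(0.84)) < 3 * se
        # line means are noisy versions of breeding values; their cross-regime
        # correlation is attenuated by sqrt(h2_mean-basis) in each regime --
        # compare against the correlation of the true genetic values instead
        r_cross = corr["cross"].loc["trait", "trait"]
        se = 1.0 / np.sqrt(cfg.n_lines - 3)
        attenuation = cfg.target_h2  # both regimes share the same h2
        assert abs(np.arctanh(r_cross) - np.arctanh(0.84 * attenuation)) < 3 * se

    def test_anticorrelated_vectors(self):
        rows = []
        vals = np.arange(10, dtype=float)
        for g, v in zip(range(10), vals):
            rows.append({"genotype": f"G{g}", "year": 2021, "block": 1,
                         "regime": "WS", "trait": "a", "value": v})
            rows.append({"genotype": f"G{g}", "year": 2021, "block": 1,
                         "regime": "WS", "trait": "b", "value": -v})
        corr = trait_correlations(PhenotypeTable(pd.DataFrame(rows)))
        assert corr["WS"].loc["a", "b"] == pytest.approx(-1.0)

    def test_too_few_pairs_flagged_nan(self):
        rows = [{"genotype": f"G{g}", "year": 2021, "block": 1, "regime": "WS",
                 "trait": t, "value": float(g)}
                for g in range(2) for t in ("a", "b")]
        corr = trait_correlations(PhenotypeTable(pd.DataFrame(rows)))
        assert np.isnan(corr["WS"].loc["a", "b"])


def test_trait_summary_is_internally_coherent(clean_sim):
    _, _, pheno, _ = clean_sim
    s = trait_summary(pheno, "trait", "WS")
    assert s.PV >= s.GV >= 0
    assert s.PCV >= s.GCV >= 0
    assert 0.0 <= s.H2 <= 1.0
    assert s.H2 == pytest.approx(s.GV / s.PV)
    assert s.range[0] <= s.mean <= s.range[1]
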