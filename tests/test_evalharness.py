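"""Cross-validation harness: metrics, determinism, leakage protection."""

import numpy as np
import pytest

from wheatgs.evalharness import (EvalScheme, accuracy_from_ability, printed_mean,
                                 run_cross_condition, run_kfcv, run_loocv,
                                 summarize)
from wheatgs.gsmodels import make_model


class OracleModel:
    """Test double that memorises y over the full line set by row identity."""

    def __init__(self, full_X, full_y):
        self.lookup = {tuple(row): v for row, v in zip(full_X, full_y)}

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.lookup[tuple(r)] for r in np.asarray(X)])


class MeanModel:
    def fit(self, X, y):
        self.c = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.c)


@pytest.fixture(scope="module")
def xy():
    rng = np.random.default_rng(3)
    X = rng.choice([0.0, 2.0], size=(60, 100))
    beta = rng.standard_normal(100) * 0.15
    y = 5 + (X - X.mean(0)) @ beta + rng.standard_normal(60) * 0.8
    return X, y


class TestAccuracyFromAbility:
    def test_published_worked_examples(self):
        assert accuracy_from_ability(0.31, 0.20) == pytest.approx(0.69, abs=0.005)
        assert accuracy_from_ability(0.84, 0.69) == pytest.approx(1.01, abs=0.005)

    def test_identity_at_full_heritability(self):
        assert accuracy_from_ability(0.42, 1.0) == 0.42

    def test_undefined_below_zero(self):
        with pytest.raises(ValueError):
            accuracy_from_ability(0.5, 0.0)


class TestPrintedMean:
    def test_row_mean_arithmetic(self):
        assert printed_mean([0.69, 0.75, 0.69, 0.62, 0.73, 0.70]) == 0.70
        assert printed_mean([0.75, 0.72, 0.63, 0.60, 0.72, 0.68]) == 0.68

    def test_single_value(self):
        assert printed_mean([0.415]) == 0.42


class TestKfcv:
    def test_oracle_predictor_scores_perfectly(self, xy):
        X, y = xy
        scheme = EvalScheme(kind="kfcv", n_iterations=20, seed=1)
        res = run_kfcv(X, y, lambda: OracleModel(X, y), scheme, h2=1.0)
        assert res.r_mp == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-12)
        assert res.r_mp_sd == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_reproduces_everything(self, xy):
        X, y = xy
        scheme = EvalScheme(kind="kfcv", n_iterations=15, seed=7)
        a = run_kfcv(X, y, lambda: make_model("rrblup"), scheme)
        b = run_kfcv(X, y, lambda: make_model("rrblup"), scheme)
        assert a.r_mp == b.r_mp and a.r_mp_sd == b.r_mp_sd and a.rmse == b.rmse

    def test_null_phenotype_centred_on_zero(self, xy):
        X, _ = xy
        rng = np.random.default_rng(10)
        y_null = rng.standard_normal(len(X))  # no genetic signal at all
        scheme = EvalScheme(kind="kfcv", n_iterations=150, seed=2)
        res = run_kfcv(X, y_null, lambda: make_model("rrblup"), scheme)
        se = res.r_mp_sd / np.sqrt(res.n_iterations_used)
        # 3-SE band plus the finite-sample floor of a correlation of 12 points
        assert abs(res.r_mp) < max(3 * se, 3.0 / np.sqrt(12 - 3))

    def test_constant_predictions_skipped_and_flagged(self, xy):
        X, y = xy
        scheme = EvalScheme(kind="kfcv", n_iterations=5, seed=3)
        res = run_kfcv(X, y, lambda: MeanModel(), scheme)
        assert res.degenerate
        assert res.n_skipped == 5

    def test_strict_kfold_mode_partitions_all_lines(self, xy):
        X, y = xy
        scheme = EvalScheme(kind="kfcv", n_iterations=10, seed=4,
                            strict_kfold=True)
        res = run_kfcv(X, y, lambda: OracleModel(X, y), scheme, h2=1.0)
        assert res.r_mp == pytest.approx(1.0)
        assert res.n_iterations_used == 10  # 2 repetitions x 5 folds


class TestLoocv:
    def test_matches_naive_double_loop(self, xy):
        """Harness LOOCV equals an explicit per-fold refit loop."""
        X, y = xy
        res = run_loocv(X, y, lambda: make_model("rrblup"), h2=0.5)
        preds = np.empty(len(y))
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            m = make_model("rrblup").fit(X[mask], y[mask])
            preds[i] = m.predict(X[i:i + 1])[0]
        assert res.r_mp == pytest.approx(np.corrcoef(preds, y)[0, 1], abs=1e-12)
        assert res.rmse == pytest.approx(np.sqrt(np.mean((preds - y) ** 2)),
                                         abs=1e-12)

    def test_oracle_predictor(self, xy):
        X, y = xy
        res = run_loocv(X, y, lambda: OracleModel(X, y), h2=1.0)
        assert res.r_mp == pytest.approx(1.0)

    def test_constant_predictor_flagged_degenerate_not_zero(self, xy):
        X, y = xy

        class ZeroModel:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.zeros(len(X))

        res = run_loocv(X, y, lambda: ZeroModel())
        assert res.degenerate
        assert np.isnan(res.r_mp)


class TestCrossCondition:
    def test_identical_regimes_reproduce_within_regime_fit(self, xy):
        X, y = xy
        res = run_cross_condition(X, y, y, lambda: make_model("rrblup"),
                                  h2_test=0.5, configuration="CWR->WW")
        m = make_model("rrblup").fit(X, y)
        r_self = np.corrcoef(m.predict(X), y)[0, 1]
        assert res.r_mp == pytest.approx(r_self, abs=1e-10)

    def test_uncorrelated_test_phenotype_near_zero(self, xy):
        X, y = xy
        rng = np.random.default_rng(8)
        y_other = rng.standard_normal(len(y))
        res = run_cross_condition(X, y, y_other, lambda: make_model("rrblup"))
        assert abs(res.r_mp) < 3.0 / np.sqrt(len(y) - 3)

    def test_mismatched_line_sets_rejected(self, xy):
        X, y = xy
        with pytest.raises(ValueError):
            run_cross_condition(X, y, y[:-1], lambda: make_model("rrblup"))

    def test_r_mg_above_one_is_flagged(self, xy):
        X, y = xy
        res = run_cross_condition(X, y, y, lambda: OracleModel(X, y),
                                  h2_test=0.5)
        assert res.r_mg == pytest.approx(1.0 / np.sqrt(0.5))
        assert res.exceeds_one


class TestLeakageCanary:
    def test_validation_only_signal_cannot_inflate_accuracy(self):
        """A marker equal to the phenotype only on validation rows must not
        help: tuning and fitting never see validation phenotypes."""
        rng = np.random.default_rng(12)
        n = 60
        X = rng.choice([0.0, 2.0], size=(n, 30))
        y = rng.standard_normal(n)  # pure noise
        scheme = EvalScheme(kind="kfcv", n_iterations=40, seed=0)
        # canary column: phenotype value on a fixed "validation half",
        # noise elsewhere -- any leak of validation y would light it up
        canary = rng.standard_normal(n)
        canary[30:] = y[30:]
        Xc = np.column_stack([X, canary])
        res = run_kfcv(Xc, y, lambda: make_model("rrblup"), scheme)
        se = res.r_mp_sd / np.sqrt(res.n_iterations_used)
        assert abs(res.r_mp) < max(4 * se, 0.35)


def test_summarize_produces_tables_and_printed_means(xy):
    X, y = xy
    scheme = EvalScheme(kind="kfcv", n_iterations=5, seed=1)
    results = [run_kfcv(X, y, lambda: make_model("rrblup"), scheme, h2=0.5,
                        trait=t, regime="WS", model_name="rrblup")
               for t in ("GY", "TKW")]
    tables = summarize(results)
    assert len(tables["long"]) == 2
    wide = tables["wide"][("kfcv", "WS", "r_MP")]
    assert set(wide.index) == {"GY", "TKW"}
    means = tables["means"]
    row = means[(means.model == "rrblup") & (means.metric == "r_MP")]
    assert row.iloc[0]["n_traits"] == 2


def test_scheme_validation():
    with pytest.raises(ValueError):
        EvalScheme(kind="bootstrap")
    with pytest.raises(ValueError):
        EvalScheme(kind="kfcv", test_fraction=1.0)
    with pytest.raises(ValueError):
        EvalScheme(kind="cross_condition", train_regime="WS", test_regime="WS")
    EvalScheme(kind="cross_condition", train_regime="CWR", test_regime="CWR")
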