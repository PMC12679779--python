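"""Cross-validation schemes and accuracy metrics for genomic prediction.

Three evaluation designs:

- **KFCV** — repeated random 80:20 subsampling (Monte-Carlo CV): in each of
  ``n_iterations`` (default 150) iterations a random 20% of lines is held
  out, the model is fitted on the other 80% and the Pearson correlation
  between predictions and observed values (the predictive ability r_MP) and
  the RMSE are recorded; the mean and SD over iterations are reported.  A
  strict disjoint k-fold mode is available behind ``strict_kfold``.
- **LOOCV** — each line is held out once; r_MP is the pooled correlation of
  the n out-of-fold predictions with the observed values (a per-fold
  correlation is undefined at n=1).
- **cross-condition** — fit on all lines' phenotypes in one water regime,
  predict all lines, correlate against the other regime's phenotypes
  (configurations WW->WS, WS->WW, CWR->WS, CWR->WW).

Prediction accuracy is r_MG = r_MP / sqrt(H2), using the regime-specific H2
for within-regime schemes and the **test** regime's H2 for cross-condition
runs; values above 1 are possible (and flagged) when r_MP is high while H2
is low.

All tuning (Bayesian hyperparameters, RKHS bandwidth, ML grids) happens
inside each training partition by construction: model factories produce
fresh models that only ever see the training fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EvalScheme", "EvalResult", "run_kfcv", "run_loocv",
           "run_cross_condition", "accuracy_from_ability", "summarize",
           "printed_mean"]

log = logging.getLogger(__name__)

SCHEME_KINDS = ("kfcv", "loocv", "cross_condition")


@dataclass
class EvalScheme:
    """Evaluation design settings."""

    kind: str = "kfcv"
    train_regime: str = "WS"
    test_regime: str = "WS"
    n_iterations: int = 150
    test_fraction: float = 0.20
    strict_kfold: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"kind must be one of {SCHEME_KINDS}")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.kind == "cross_condition":
            if self.train_regime == self.test_regime and self.train_regime != "CWR":
                raise ValueError("cross_condition needs train != test regime "
                                 "(or training on CWR)")


@dataclass
class EvalResult:
    """Per trait x regime x model x scheme evaluation outcome."""

    trait: str
    regime: str            # "WS", "WW", "CWR" or "WW->WS" style for cross runs
    model: str
    scheme: str
    r_mp: float
    r_mp_sd: float = np.nan
    r_mg: float = np.nan
    rmse: float = np.nan
    n_lines: int = 0
    h2: float = np.nan
    n_iterations_used: int = 0
    n_skipped: int = 0
    degenerate: bool = False
    exceeds_one: bool = field(init=False, default=False)

    def __post_init__(self):
        self.exceeds_one = bool(np.isfinite(self.r_mg) and abs(self.r_mg) > 1.0)

    def as_dict(self) -> dict:
        return {
            "trait": self.trait, "regime": self.regime, "model": self.model,
            "scheme": self.scheme, "r_MP": self.r_mp, "r_MP_sd": self.r_mp_sd,
            "r_MG": self.r_mg, "RMSE": self.rmse, "H2": self.h2,
            "n_lines": self.n_lines, "n_iterations": self.n_iterations_used,
            "n_skipped": self.n_skipped, "degenerate": self.degenerate,
        }


def accuracy_from_ability(r_mp: float, h2: float) -> float:
    """Prediction accuracy r_MG = r_MP / sqrt(H2); requires H2 > 0.

    Values with magnitude above 1 are legitimate outputs (high predictive
    ability with low heritability) and are flagged on the EvalResult.
    """
    if not h2 > 0:
        raise ValueError("r_MG undefined for H2 <= 0")
    return r_mp / np.sqrt(h2)


def _degenerate(x: np.ndarray) -> bool:
    # summation rounding can leave a ~1e-17 std on identical values
    return np.std(x) <= 1e-12 * max(1.0, float(np.abs(x).max(initial=0.0)))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if _degenerate(a) or _degenerate(b):
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def run_kfcv(X, y, model_factory, scheme: EvalScheme, h2: float = np.nan,
             trait: str = "trait", regime: str = "", model_name: str = "") -> EvalResult:
    """Repeated 80:20 cross-validation.

    ``model_factory()`` must return a fresh unfitted model exposing
    ``fit(X, y)`` and ``predict(X)``; it is called once per iteration and
    only ever sees the training fold.  Iterations whose test fold has fewer
    than 3 lines, or where predictions are constant, are skipped and
    counted.  The split sequence is a pure function of ``scheme.seed``.
    """
    if scheme.kind != "kfcv":
        raise ValueError("scheme.kind must be 'kfcv'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(scheme.seed)
    n_test = int(round(scheme.test_fraction * n))

    rs, rmses, skipped = [], [], 0
    if scheme.strict_kfold:
        k = max(2, int(round(1.0 / scheme.test_fraction)))
        reps = max(1, scheme.n_iterations // k)
        splits = []
        for _ in range(reps):
            perm = rng.permutation(n)
            splits.extend(np.array_split(perm, k))
    else:
        splits = [rng.permutation(n)[:n_test] for _ in range(scheme.n_iterations)]

    for test_idx in splits:
        if len(test_idx) < 3:
            skipped += 1
            log.info("kfcv: skipped iteration with %d test lines", len(test_idx))
            continue
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        pred = np.asarray(model.predict(X[test_idx]), dtype=float)
        r = _pearson(pred, y[test_idx])
        if np.isnan(r):
            skipped += 1
            log.info("kfcv: skipped iteration with degenerate predictions")
            continue
        rs.append(r)
        rmses.append(_rmse(pred, y[test_idx]))

    if not rs:
        return EvalResult(trait, regime, model_name, "kfcv", np.nan,
                          n_lines=n, n_skipped=skipped, degenerate=True)
    r_mp = float(np.mean(rs))
    r_mg = accuracy_from_ability(r_mp, h2) if h2 > 0 else np.nan
    return EvalResult(
        trait=trait, regime=regime, model=model_name, scheme="kfcv",
        r_mp=r_mp, r_mp_sd=float(np.std(rs, ddof=1)) if len(rs) > 1 else np.nan,
        r_mg=r_mg, rmse=float(np.mean(rmses)), n_lines=n, h2=h2,
        n_iterations_used=len(rs), n_skipped=skipped,
    )


def run_loocv(X, y, model_factory, h2: float = np.nan, trait: str = "trait",
              regime: str = "", model_name: str = "") -> EvalResult:
    """Leave-one-out cross-validation with pooled r_MP.

    A model failure on a fold is recorded and the fold excluded; constant
    pooled predictions make r_MP undefined (flagged ``degenerate`` rather
    than reported as 0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 lines")
    preds = np.full(n, np.nan)
    failures = 0
    for i in range(n):
        train_idx = np.r_[0:i, i + 1:n]
        model = model_factory()
        try:
            model.fit(X[train_idx], y[train_idx])
            preds[i] = float(np.asarray(model.predict(X[i:i + 1]))[0])
        except Exception as exc:  # noqa: BLE001 - fold failures are data, not bugs
            failures += 1
            log.warning("loocv: fold %d failed: %s", i, exc)
    ok = ~np.isnan(preds)
    r_mp = _pearson(preds[ok], y[ok]) if ok.sum() >= 3 else np.nan
    degenerate = bool(np.isnan(r_mp))
    r_mg = accuracy_from_ability(r_mp, h2) if (h2 > 0 and not degenerate) else np.nan
    return EvalResult(
        trait=trait, regime=regime, model=model_name, scheme="loocv",
        r_mp=r_mp, r_mg=r_mg,
        rmse=_rmse(preds[ok], y[ok]) if ok.any() else np.nan,
        n_lines=n, h2=h2, n_iterations_used=int(ok.sum()), n_skipped=failures,
        degenerate=degenerate,
    )


def run_cross_condition(X, y_train, y_test, model_factory, h2_test: float = np.nan,
                        trait: str = "trait", configuration: str = "WW->WS",
                        model_name: str = "") -> EvalResult:
    """Train on one regime's line means, test on the other regime's.

    ``y_train`` and ``y_test`` must be aligned to the same lines (rows of
    ``X``); r_MG uses the test regime's heritability, which reproduces the
    possibility of accuracies above 1.
    """
    X = np.asarray(X, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if not (len(y_train) == len(y_test) == X.shape[0]):
        raise ValueError("regime phenotypes must cover the same line set")
    model = model_factory()
    model.fit(X, y_train)
    pred = np.asarray(model.predict(X), dtype=float)
    r_mp = _pearson(pred, y_test)
    degenerate = bool(np.isnan(r_mp))
    r_mg = accuracy_from_ability(r_mp, h2_test) if (h2_test > 0 and not degenerate) else np.nan
    if np.isfinite(r_mg) and abs(r_mg) > 1:
        log.info("cross-condition %s %s: r_MG=%.2f exceeds 1", configuration,
                 trait, r_mg)
    return EvalResult(
        trait=trait, regime=configuration, model=model_name,
        scheme="cross_condition", r_mp=r_mp, r_mg=r_mg,
        rmse=_rmse(pred, y_test), n_lines=len(y_test), h2=h2_test,
        degenerate=degenerate,
    )


def summarize(results, round_to: int = 2):
    """Long- and wide-format report tables from a list of EvalResults.

    Returns a dict with the long table, one wide trait x model grid per
    (scheme, regime) for each metric, and per-regime / grand means.  Regime
    means follow printed-table arithmetic: trait values are rounded to
    ``round_to`` decimals before averaging; full-precision means are
    reported alongside.
    """
    long = pd.DataFrame([r.as_dict() for r in results])
    out = {"long": long}
    wide = {}
    means = []
    for (scheme, regime), grp in long.groupby(["scheme", "regime"]):
        for metric in ("r_MP", "r_MG", "RMSE"):
            wide[(scheme, regime, metric)] = grp.pivot_table(
                index="trait", columns="model", values=metric, aggfunc="first"
            )
        for model, mg in grp.groupby("model"):
            for metric in ("r_MP", "r_MG", "RMSE"):
                vals = mg[metric].dropna()
                if vals.empty:
                    continue
                means.append({
                    "scheme": scheme, "regime": regime, "model": model,
                    "metric": metric,
                    "mean_printed": float(np.round(vals.round(round_to).mean(),
                                                   round_to)),
                    "mean_full": float(vals.mean()),
                    "n_traits": len(vals),
                })
    out["wide"] = wide
    out["means"] = pd.DataFrame(means)
    if not out["means"].empty:
        grand = (
            out["means"]
            .groupby(["scheme", "model", "metric"], as_index=False)[
                ["mean_printed", "mean_full"]]
            .mean()
        )
        out["grand_means"] = grand
    return out


def printed_mean(values, round_to: int = 2) -> float:
    """Mean of already-rounded table values, rounded again for printing.

    Mirrors how summary rows of published tables are computed from the
    printed per-trait entries.
    """
    vals = np.round(np.asarray(values, dtype=float), round_to)
    return float(np.round(np.mean(vals), round_to))
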