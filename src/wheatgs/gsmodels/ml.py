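"""Machine-learning regressors with inner-CV hyperparameter tuning.

Random forest, RBF-kernel support-vector regression and gradient-boosted
trees, delegated to scikit-learn and xgboost, wrapped so that tuning
happens strictly inside the training partition: the grid search sees only
the data passed to ``fit`` and selects hyperparameters by minimum RMSE in
inner cross-validation.

Default grids follow common practice for genomic prediction: the random
forest searches maximum depth {40, 60, 80, 100}, feature subsampling
{p/3 ("auto" for regression), sqrt(p)} and {200, 300, 500, 1000} trees.
The SVR uses C = 1 with kernel width gamma = 1 / (p * var(X)) (inputs are
standardized) plus an optional small grid; XGBoost tunes depth, learning
rate and tree count over a compact grid with squared-error loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold, ParameterGrid
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

__all__ = ["MLModel", "fit_ml", "DEFAULT_GRIDS", "ML_TAGS"]

ML_TAGS = ("rf", "svm", "xgb")

DEFAULT_GRIDS = {
    "rf": {
        "max_depth": [40, 60, 80, 100],
        "max_features": [1.0 / 3.0, "sqrt"],   # "auto" (p/3 for regression) and sqrt(p)
        "n_estimators": [200, 300, 500, 1000],
    },
    "svm": {
        "svr__C": [1.0],
        "svr__gamma": ["scale"],               # 1 / (p * var(X)) after standardization
    },
    "xgb": {
        "max_depth": [2, 4, 6],
        "learning_rate": [0.05, 0.1],
        "n_estimators": [100, 300],
    },
}


def _base_estimator(tag: str, seed: int):
    if tag == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1)
    if tag == "svm":
        return Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
    if tag == "xgb":
        return XGBRegressor(
            objective="reg:squarederror",
            reg_lambda=1.0,
            gamma=0.0,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise ValueError(f"algorithm must be one of {ML_TAGS}")


@dataclass
class MLModel:
    """A tuned, fitted machine-learning regressor."""

    algorithm: str
    best_params: dict
    estimator: object = field(repr=False, default=None)
    constant: float | None = None          # set for degenerate (zero-variance) y
    marker_ids: list = None

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X_new, dtype=float)),
                          dtype=float)


def fit_ml(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str,
    grid: dict | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    marker_ids=None,
) -> MLModel:
    """Tune and fit one ML regressor by minimum inner-CV RMSE.

    Trees see raw {0, 2} dosages (scale-invariant); the SVR standardizes
    inputs inside its pipeline.  A zero-variance ``y`` yields a constant
    predictor with a warning.
    """
    if algorithm not in ML_TAGS:
        raise ValueError(f"algorithm must be one of {ML_TAGS}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = dict(DEFAULT_GRIDS[algorithm]) if grid is None else dict(grid)

    if np.var(y) == 0:
        warnings.warn(f"{algorithm}: zero-variance response, fitting a constant",
                      stacklevel=2)
        est = DummyRegressor(strategy="mean").fit(X, y)
        return MLModel(algorithm=algorithm, best_params={}, estimator=est,
                       constant=float(y.mean()),
                       marker_ids=list(marker_ids) if marker_ids is not None else None)

    base = _base_estimator(algorithm, seed)
    n_candidates = len(list(ParameterGrid(grid)))
    if n_candidates <= 1 or len(y) < 2 * inner_folds:
        params = {k: v[0] for k, v in grid.items()}
        est = base.set_params(**params).fit(X, y)
        best = params
    else:
        search = GridSearchCV(
            base,
            grid,
            scoring="neg_root_mean_squared_error",
            cv=KFold(n_splits=inner_folds, shuffle=True, random_state=seed),
            n_jobs=1,
            refit=True,
        )
        search.fit(X, y)
        est = search.best_estimator_
        best = search.best_params_
    return MLModel(algorithm=algorithm, best_params=dict(best), estimator=est,
                   marker_ids=list(marker_ids) if marker_ids is not None else None)
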