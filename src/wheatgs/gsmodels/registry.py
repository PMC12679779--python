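"""Uniform construction of the ten genomic prediction models by name."""

from __future__ import annotations

import numpy as np

from wheatgs.gsmodels.base import GenomicModel
from wheatgs.gsmodels.bayes import ChainSettings, fit_bayes
from wheatgs.gsmodels.kernel import DEFAULT_FACTORS, fit_rkhs
from wheatgs.gsmodels.ml import fit_ml
from wheatgs.gsmodels.rrblup import fit_rrblup

__all__ = ["MODEL_NAMES", "make_model"]

MODEL_NAMES = (
    "rrblup",
    "bayes_a", "bayes_b", "bayes_c", "brr", "bayes_lasso",
    "rkhs",
    "rf", "svm", "xgb",
)

_BAYES_TAG = {"bayes_a": "A", "bayes_b": "B", "bayes_c": "C",
              "brr": "BRR", "bayes_lasso": "LASSO"}


class RRBLUPModel(GenomicModel):
    name = "rrblup"

    def __init__(self, **_ignored):
        super().__init__()
        self.state = None

    def _fit(self, X, y):
        self.state = fit_rrblup(X, y)

    def _predict(self, X):
        return self.state.predict(X)


class BayesModel(GenomicModel):
    def __init__(self, name: str, n_iter=30_000, burn_in=10_000, thin=5,
                 seed=0, **kwargs):
        super().__init__()
        self.name = name
        self.tag = _BAYES_TAG[name]
        self.chain = ChainSettings(n_iter=n_iter, burn_in=burn_in, thin=thin,
                                   seed=seed)
        self.kwargs = kwargs
        self.state = None

    def _fit(self, X, y):
        self.state = fit_bayes(X, y, self.tag, settings=self.chain, **self.kwargs)

    def _predict(self, X):
        return self.state.predict(X)


class RKHSModel(GenomicModel):
    name = "rkhs"

    def __init__(self, factors=DEFAULT_FACTORS, inner_folds=5, seed=0, **_ignored):
        super().__init__()
        self.factors = factors
        self.inner_folds = inner_folds
        self.seed = seed
        self.state = None

    def _fit(self, X, y):
        self.state = fit_rkhs(X, y, factors=self.factors,
                              inner_folds=self.inner_folds, seed=self.seed)

    def _predict(self, X):
        return self.state.predict(X)


class SkMLModel(GenomicModel):
    def __init__(self, name: str, grid=None, inner_folds=5, seed=0, **_ignored):
        super().__init__()
        self.name = name
        self.grid = grid
        self.inner_folds = inner_folds
        self.seed = seed
        self.state = None

    def _fit(self, X, y):
        self.state = fit_ml(X, y, self.name, grid=self.grid,
                            inner_folds=self.inner_folds, seed=self.seed)

    def _predict(self, X):
        return self.state.predict(X)


def make_model(name: str, seed: int = 0, **params) -> GenomicModel:
    """Construct an unfitted model by registry name.

    ``params`` are forwarded to the model constructor (chain settings for
    the Bayesian models, bandwidth factors for RKHS, tuning grids for the
    ML models).  Seeds make stochastic models bit-reproducible.
    """
    name = name.lower()
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    if name == "rrblup":
        return RRBLUPModel(**params)
    if name in _BAYES_TAG:
        return BayesModel(name, seed=seed, **params)
    if name == "rkhs":
        return RKHSModel(seed=seed, **params)
    return SkMLModel(name, seed=seed, **params)


def _selfcheck():  # pragma: no cover - convenience for interactive use
    rng = np.random.default_rng(0)
    X = rng.choice([0.0, 2.0], size=(30, 40))
    y = X[:, 0] + rng.standard_normal(30)
    for n in MODEL_NAMES:
        m = make_model(n, n_iter=200, burn_in=100)
        m.fit(X, y)
        m.predict(X)
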