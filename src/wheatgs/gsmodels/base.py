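"""Common model interface and marker-ID alignment."""

from __future__ import annotations

import abc

import numpy as np

__all__ = ["GenomicModel", "MarkerAlignmentError", "align_markers"]


class MarkerAlignmentError(ValueError):
    """New data's marker set does not match the fitted model's."""


def align_markers(X: np.ndarray, new_ids, fitted_ids) -> np.ndarray:
    """Reorder columns of ``X`` (indexed by ``new_ids``) to ``fitted_ids``.

    Alignment is by marker ID: a consistent permutation is accepted, any
    set difference raises :class:`MarkerAlignmentError` listing the
    offending IDs.  With no IDs on either side, column order is trusted.
    """
    if fitted_ids is None or new_ids is None:
        return X
    new_ids, fitted_ids = list(new_ids), list(fitted_ids)
    if new_ids == fitted_ids:
        return X
    missing = [m for m in fitted_ids if m not in set(new_ids)]
    extra = [m for m in new_ids if m not in set(fitted_ids)]
    if missing or extra:
        raise MarkerAlignmentError(
            f"marker set mismatch: missing from new data {missing[:10]}"
            f"{'...' if len(missing) > 10 else ''}; unseen {extra[:10]}"
            f"{'...' if len(extra) > 10 else ''}"
        )
    pos = {m: i for i, m in enumerate(new_ids)}
    order = [pos[m] for m in fitted_ids]
    return X[:, order]


class GenomicModel(abc.ABC):
    """A trained (or trainable) genomic predictor.

    Subclasses implement ``_fit`` / ``_predict`` on numpy arrays; marker-ID
    bookkeeping and validation live here.
    """

    name: str = "model"

    def __init__(self):
        self._fitted = False
        self._marker_ids = None

    def fit(self, X, y, marker_ids=None) -> "GenomicModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be n x m with len(y) == n")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute first")
        if marker_ids is not None and len(marker_ids) != X.shape[1]:
            raise ValueError("marker_ids length does not match X columns")
        self._marker_ids = list(marker_ids) if marker_ids is not None else None
        self._fit(X, y)
        self._fitted = True
        return self

    def predict(self, X, marker_ids=None) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError(f"{self.name}: predict called before fit")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        X = align_markers(X, marker_ids, self._marker_ids)
        return self._predict(X)

    @abc.abstractmethod
    def _fit(self, X: np.ndarray, y: np.ndarray) -> None: ...

    @abc.abstractmethod
    def _predict(self, X: np.ndarray) -> np.ndarray: ...
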