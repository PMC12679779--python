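"""RR-BLUP: ridge-regression BLUP with the ridge parameter set by REML.

Model: y = 1 mu + Z u + eps with u ~ N(0, I sigma2_u), eps ~ N(0, I sigma2_e)
on column-centred dosages Z.  Variance components are estimated by REML on
the spectral decomposition of Z Z' (the profiled restricted likelihood is a
one-dimensional function of the variance ratio delta = sigma2_e / sigma2_u),
and marker effects are the mixed-model-equation solution

    u = Z' (Z Z' + lambda I)^{-1} (y - 1 mu),    lambda = sigma2_e / sigma2_u.

The same spectral REML applies to any line-by-line covariance K (GBLUP /
kernel regression); :func:`kinship_blup` exposes that form, which RR-BLUP is
exactly equivalent to when K = Z Z' / c with a matched variance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["MarkerModel", "fit_rrblup", "kinship_blup", "spectral_reml"]


def spectral_reml(K: np.ndarray, y: np.ndarray):
    """REML for y = 1 mu + g + e with g ~ N(0, s2_k K), e ~ N(0, s2_e I).

    Returns ``(mu, s2_k, s2_e, alpha)`` where predictions for lines with
    covariance rows ``K_new`` (against training lines) are
    ``mu + K_new @ alpha``.

    The intercept is projected out and the restricted likelihood profiled
    over ``delta = s2_e / s2_k`` on the eigenbasis of the projected K; the
    1-D profile is maximised numerically.  A constant y yields s2_k = 0 and
    constant predictions.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K.shape != (n, n):
        raise ValueError("K must be n x n")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not np.any(np.abs(K) > 1e-12):
        raise ValueError("K is identically zero (rank-0 marker matrix?)")
    if np.var(y) < 1e-14 * max(1.0, abs(y.mean())) ** 2:
        return y.mean(), 0.0, float(np.var(y)), np.zeros(n)

    # restricted likelihood on contrasts: A is an orthonormal basis of the
    # complement of the intercept (Householder reflection sending e1 to
    # 1/sqrt(n)), so A'1 = 0 and w = A'y ~ N(0, s2_k A'KA + s2_e I)
    v = -np.ones(n) / np.sqrt(n)
    v[0] += 1.0
    v /= np.linalg.norm(v)
    H = np.eye(n) - 2.0 * np.outer(v, v)
    A = H[:, 1:]
    s, U = np.linalg.eigh(A.T @ K @ A)
    s = np.clip(s, 0.0, None)
    yr = U.T @ (A.T @ y)
    m = n - 1

    def neg_profile(log_delta: float) -> float:
        delta = np.exp(log_delta)
        d = s + delta
        return float(np.log(d).sum() + m * np.log((yr**2 / d).sum()))

    # the lower bound floors delta at 1e-6 x the top eigenvalue: below that
    # the profile is flat to rounding and V becomes numerically singular
    span = max(s.max(), 1e-8)
    res = optimize.minimize_scalar(
        neg_profile, bounds=(np.log(span) - 14.0, np.log(span) + 25.0),
        method="bounded", options={"xatol": 1e-10},
    )
    delta = float(np.exp(res.x))
    d = s + delta
    s2_k = float((yr**2 / d).sum() / m)
    s2_e = delta * s2_k

    V = s2_k * K + s2_e * np.eye(n)
    Vi_y = np.linalg.solve(V, y)
    Vi_1 = np.linalg.solve(V, np.ones(n))
    mu = float((np.ones(n) @ Vi_y) / (np.ones(n) @ Vi_1))
    alpha = s2_k * np.linalg.solve(V, y - mu)
    return mu, s2_k, s2_e, alpha


@dataclass
class MarkerModel:
    """Fitted RR-BLUP model."""

    mu: float
    u: np.ndarray                 # per-marker effects, trait units per dosage
    sigma2_u: float
    sigma2_e: float
    lambda_: float                # sigma2_e / sigma2_u
    col_means: np.ndarray = field(repr=False, default=None)
    marker_ids: list = None

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        return self.mu + (X_new - self.col_means) @ self.u


def fit_rrblup(X: np.ndarray, y: np.ndarray, marker_ids=None) -> MarkerModel:
    """Fit RR-BLUP on raw dosages (centred internally).

    Raises on an all-constant (rank-0 after centring) marker matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    col_means = X.mean(axis=0)
    Z = X - col_means
    if not np.any(np.abs(Z) > 1e-12):
        raise ValueError("marker matrix has no variation (all-constant columns)")
    K = Z @ Z.T
    mu, s2_u, s2_e, alpha = spectral_reml(K, y)
    # alpha = s2_u V^{-1}(y - mu), so u = s2_u Z' V^{-1}(y - mu) = Z' alpha
    u = Z.T @ alpha if s2_u > 0 else np.zeros(Z.shape[1])
    lam = s2_e / s2_u if s2_u > 0 else np.inf
    return MarkerModel(
        mu=mu, u=u, sigma2_u=s2_u, sigma2_e=s2_e, lambda_=lam,
        col_means=col_means,
        marker_ids=list(marker_ids) if marker_ids is not None else None,
    )


@dataclass
class KinshipModel:
    """Fitted kinship-form BLUP (GBLUP)."""

    mu: float
    alpha: np.ndarray
    sigma2_k: float
    sigma2_e: float

    def predict(self, K_new: np.ndarray) -> np.ndarray:
        """Predict from covariance rows of new lines against training lines."""
        return self.mu + np.asarray(K_new, dtype=float) @ self.alpha


def kinship_blup(K: np.ndarray, y: np.ndarray) -> KinshipModel:
    """GBLUP on an arbitrary line-by-line covariance matrix."""
    mu, s2_k, s2_e, alpha = spectral_reml(K, y)
    return KinshipModel(mu=mu, alpha=alpha, sigma2_k=s2_k, sigma2_e=s2_e)
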