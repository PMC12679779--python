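"""Whole-genome Bayesian regression via single-site Gibbs sampling.

All five models share the linear model y = 1 mu + Z u + eps on centred
dosages Z, eps ~ N(0, I sigma2_e), and differ only in the prior on the
marker effects u:

- **BRR**      u_j ~ N(0, sigma2_u), one shared variance (ridge-like);
- **Bayes A**  u_j ~ N(0, sigma2_j), per-marker variances with a
  scaled-inverse-chi-square prior (marginally a scaled-t);
- **Bayes B**  spike-and-slab: u_j = 0 with probability pi, otherwise
  N(0, sigma2_j) with per-marker variances (t slab);
- **Bayes C**  spike-and-slab with a common slab variance (Gaussian slab
  by default; a per-marker-variance t slab is available via
  ``slab="t"``, matching descriptions of Bayes C with a scaled-t
  non-zero component);
- **Bayesian LASSO**  u_j ~ Laplace(0, lambda), implemented through the
  scale-mixture-of-normals augmentation u_j | tau2_j ~ N(0, sigma2_e
  tau2_j), tau2_j ~ Exp(lambda^2 / 2), with a Gamma hyperprior on
  lambda^2.

Hyperpriors follow the conventions of standard whole-genome regression
software: scaled-inverse-chi-square priors with 5 degrees of freedom and
scales set from the phenotypic variance assuming half the variance is
genetic; the mixing probability pi gets a weak Beta prior (prior count 10,
mean 0.5) and is sampled unless fixed.  Chains default to 30,000 iterations
with 10,000 burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChainSettings", "BayesState", "fit_bayes", "BAYES_TAGS"]

BAYES_TAGS = ("A", "B", "C", "BRR", "LASSO")


@dataclass
class ChainSettings:
    n_iter: int = 30_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class BayesState:
    """Posterior summaries of one Gibbs run."""

    model_tag: str
    settings: ChainSettings
    priors: dict
    mu: float
    u: np.ndarray                    # posterior-mean marker effects
    marker_vars: np.ndarray          # posterior-mean per-marker prior variances
    inclusion_prob: np.ndarray       # P(u_j != 0 | data); ones for non-mixture models
    sigma2_u: float                  # posterior mean shared/average marker variance
    sigma2_e: float
    pi: float                        # posterior mean P(effect == 0); 0 if not a mixture
    n_samples: int = 0
    col_means: np.ndarray = field(repr=False, default=None)
    marker_ids: list = None

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        return self.mu + (X_new - self.col_means) @ self.u


def _sc_inv_chi2(rng, df: float, scale_times_df: float) -> float:
    """Draw sigma2 ~ ScInvChi2: (S*df + SS) / chi2_(df + n) collapses here
    to scale_times_df / chi2_df draws."""
    return scale_times_df / rng.chisquare(df)


def fit_bayes(
    X: np.ndarray,
    y: np.ndarray,
    model_tag: str,
    settings: ChainSettings | None = None,
    marker_ids=None,
    pi0: float = 0.5,
    fix_pi: bool = False,
    df_u: float = 5.0,
    df_e: float = 5.0,
    r2: float = 0.5,
    slab: str = "gaussian",
    fixed_var: tuple | None = None,
) -> BayesState:
    """Run the Gibbs sampler for one Bayesian-alphabet model.

    Parameters
    ----------
    X, y : raw dosage matrix (centred internally) and line means.
    model_tag : one of ``"A", "B", "C", "BRR", "LASSO"``.
    pi0, fix_pi : prior mean of the zero-effect probability for B/C and
        whether to keep it fixed instead of sampling it.
    df_u, df_e, r2 : hyperprior degrees of freedom and the assumed
        proportion of variance that is genetic (sets prior scales).
    slab : for Bayes C, ``"gaussian"`` (common slab variance, the default)
        or ``"t"`` (per-marker slab variances).
    fixed_var : optional ``(sigma2_u, sigma2_e)`` to hold the variance
        components fixed (supported for BRR; used to check the conjugate
        limit against RR-BLUP).

    Raises on divergence (non-finite draws), reporting the iteration.
    """
    model_tag = model_tag.upper()
    if model_tag not in BAYES_TAGS:
        raise ValueError(f"model_tag must be one of {BAYES_TAGS}")
    if fixed_var is not None and model_tag != "BRR":
        raise ValueError("fixed_var is only supported for BRR")
    if not (0.0 <= pi0 <= 1.0):
        raise ValueError("pi0 must be in [0, 1]")
    settings = settings or ChainSettings()
    rng = np.random.default_rng(settings.seed)

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    col_means = X.mean(axis=0)
    Z = np.asfortranarray(X - col_means)
    xtx = (Z**2).sum(axis=0)
    var_y = float(np.var(y))
    if var_y == 0:
        var_y = 1e-8
    msx = float((xtx / n).sum()) or 1.0

    mixture = model_tag in ("B", "C")
    per_marker_var = model_tag in ("A", "B") or (model_tag == "C" and slab == "t")

    # prior scales: S*df chosen so the prior mode hits the variance split
    S_e_df = var_y * (1.0 - r2) * (df_e + 2.0)
    genic = var_y * r2 / msx
    if mixture and pi0 < 1.0:
        genic = genic / max(1e-8, 1.0 - pi0)
    S_u_df = genic * (df_u + 2.0)

    # state
    mu = float(y.mean())
    u = np.zeros(p)
    resid = y - mu
    sigma2_e = var_y * (1.0 - r2)
    sigma2_u = genic
    marker_var = np.full(p, genic)
    incl = np.ones(p, dtype=bool)
    pi = pi0 if mixture else 0.0
    if fixed_var is not None:
        sigma2_u, sigma2_e = map(float, fixed_var)
        marker_var[:] = sigma2_u

    # Bayesian LASSO state
    if model_tag == "LASSO":
        lam2 = 2.0 * (1.0 - r2) / max(r2, 1e-8) * msx  # lambda^2 init
        tau2 = np.full(p, 1.0 / max(lam2, 1e-8))
        a_l, b_l = 1.1, 0.1 / max(lam2, 1e-8)

    # Beta prior counts for pi (prior weight 10, mean pi0)
    a_pi, b_pi = 10.0 * pi0 + 1e-6, 10.0 * (1.0 - pi0) + 1e-6

    keep = 0
    sum_u = np.zeros(p)
    sum_mu = 0.0
    sum_var = np.zeros(p)
    sum_incl = np.zeros(p)
    sum_s2u = 0.0
    sum_s2e = 0.0
    sum_pi = 0.0

    log_pi_ratio = 0.0
    for it in range(settings.n_iter):
        # intercept
        e_mu = resid + mu
        mu = e_mu.mean() + rng.standard_normal() * np.sqrt(sigma2_e / n)
        resid = e_mu - mu

        if mixture:
            cur_pi = pi
            log_pi_ratio = np.log((1.0 - cur_pi) / cur_pi) if 0.0 < cur_pi < 1.0 else (
                np.inf if cur_pi == 0.0 else -np.inf)

        # marker effects
        for j in range(p):
            zj = Z[:, j]
            if xtx[j] == 0.0:
                u[j] = 0.0
                incl[j] = False if mixture else True
                continue
            if u[j] != 0.0:
                resid += zj * u[j]
            rhs = zj @ resid
            if model_tag == "LASSO":
                lam_j = 1.0 / tau2[j]
            else:
                vj = marker_var[j] if per_marker_var else sigma2_u
                lam_j = sigma2_e / vj
            C = xtx[j] + lam_j

            if mixture:
                if cur_pi >= 1.0:
                    take = False
                elif cur_pi <= 0.0:
                    take = True
                else:
                    log_bf = 0.5 * (rhs * rhs) / (sigma2_e * C) \
                        + 0.5 * np.log(lam_j / C)
                    logit = log_pi_ratio + log_bf
                    if logit > 35:
                        take = True
                    elif logit < -35:
                        take = False
                    else:
                        take = rng.random() < 1.0 / (1.0 + np.exp(-logit))
                incl[j] = take
                if not take:
                    u[j] = 0.0
                    continue
            u[j] = rhs / C + rng.standard_normal() * np.sqrt(sigma2_e / C)
            resid -= zj * u[j]

        # marker-variance updates
        if model_tag == "LASSO":
            uj2 = np.maximum(u * u, 1e-12)
            inv_tau2 = rng.wald(np.sqrt(lam2 * sigma2_e / uj2), lam2)
            tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)
            lam2 = rng.gamma(a_l + p, 1.0 / (b_l + tau2.sum() / 2.0))
        elif per_marker_var:
            # included markers get a data-informed draw, excluded ones a
            # fresh prior draw
            chi = rng.chisquare(df_u + incl.astype(float))
            marker_var = (S_u_df + u * u) / chi
        elif fixed_var is None:
            if mixture:  # Bayes C, Gaussian slab
                m_act = int(incl.sum())
                sigma2_u = _sc_inv_chi2(rng, df_u + m_act,
                                        S_u_df + float((u[incl] ** 2).sum()))
            else:        # BRR
                sigma2_u = _sc_inv_chi2(rng, df_u + p, S_u_df + float((u**2).sum()))

        if mixture and not fix_pi:
            n_zero = p - int(incl.sum())
            pi = rng.beta(a_pi + n_zero, b_pi + (p - n_zero))

        if fixed_var is None:
            sigma2_e = _sc_inv_chi2(rng, df_e + n, S_e_df + float(resid @ resid))

        if not np.isfinite(sigma2_e) or not np.isfinite(u).all():
            raise FloatingPointError(f"sampler diverged at iteration {it}")

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            keep += 1
            sum_u += u
            sum_mu += mu
            sum_incl += incl
            sum_s2e += sigma2_e
            if model_tag == "LASSO":
                sum_var += sigma2_e * tau2
                sum_s2u += sigma2_e * tau2.mean()
            elif per_marker_var:
                sum_var += marker_var
                sum_s2u += marker_var.mean()
            else:
                sum_var += sigma2_u
                sum_s2u += sigma2_u
            sum_pi += pi

    priors = {"df_u": df_u, "df_e": df_e, "r2": r2, "pi0": pi0,
              "fix_pi": fix_pi, "slab": slab if model_tag == "C" else None,
              "S_u_df": S_u_df, "S_e_df": S_e_df}
    return BayesState(
        model_tag=model_tag,
        settings=settings,
        priors=priors,
        mu=sum_mu / keep,
        u=sum_u / keep,
        marker_vars=sum_var / keep,
        inclusion_prob=sum_incl / keep,
        sigma2_u=sum_s2u / keep,
        sigma2_e=sum_s2e / keep,
        pi=sum_pi / keep if mixture else 0.0,
        n_samples=keep,
        col_means=col_means,
        marker_ids=list(marker_ids) if marker_ids is not None else None,
    )
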