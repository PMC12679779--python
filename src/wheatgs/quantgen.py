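"""Variance components, broad-sense heritability and trait correlations.

Plot-level data from a randomized-complete-block trial repeated over years
are analysed with the linear mixed model

    y_ikj = mu + g_i + y_k + (gy)_ik + b_j(k) + eps_ikj

where genotype ``g_i ~ N(0, sigma2_g)``, year ``y_k ~ N(0, sigma2_y)``,
genotype-by-year ``(gy)_ik ~ N(0, sigma2_gy)``, block-within-year
``b_j(k) ~ N(0, sigma2_b)`` and residual ``eps ~ N(0, sigma2_e)``.  All
non-intercept terms are random; components are estimated by REML with
non-negativity constraints (direct maximisation of the restricted
log-likelihood).

Broad-sense heritability on an entry-mean basis is

    H2 = sigma2_g / (sigma2_g + sigma2_gy / e + sigma2_e / (r * e))

with ``e`` years and ``r`` replicates (blocks) per year.  The genotypic /
phenotypic / environmental variances used for coefficients of variation are
GV = sigma2_g, PV = the H2 denominator (so H2 = GV / PV) and EV = sigma2_e.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from wheatgs.phenotypes import CWR, PhenotypeTable

__all__ = [
    "VarianceComponents",
    "TraitSummary",
    "fit_mixed_model",
    "anova_components",
    "heritability",
    "cv_coefficients",
    "trait_summary",
    "variance_table",
    "trait_correlations",
]

COMPONENT_NAMES = ("sigma2_g", "sigma2_y", "sigma2_gy", "sigma2_b", "sigma2_e")


@dataclass
class VarianceComponents:
    """REML (or method-of-moments) variance components for one trait x regime."""

    sigma2_g: float
    sigma2_y: float
    sigma2_gy: float
    sigma2_b: float
    sigma2_e: float
    e_years: int
    r_reps: int
    converged: bool = True
    single_year: bool = False
    loglik: float = np.nan

    def __post_init__(self):
        for name in COMPONENT_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.e_years < 1 or self.r_reps < 1:
            raise ValueError("e_years and r_reps must be >= 1")

    def as_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in COMPONENT_NAMES}


@dataclass
class TraitSummary:
    """Row of a genetic-variability table for one trait x regime."""

    trait: str
    regime: str
    mean: float
    se: float
    range: tuple
    GV: float
    PV: float
    EV: float
    GCV: float
    PCV: float
    ECV: float
    H2: float
    components: VarianceComponents = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


def _one_hot(labels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(labels, sort=True)
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _reml_neg2ll(theta: np.ndarray, ZZt: list, y: np.ndarray) -> float:
    """-2x restricted log-likelihood (up to a constant) for X = intercept."""
    from scipy.linalg import cho_factor, cho_solve

    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], ZZt):
        V += t * G
    # small jitter keeps the Cholesky stable when components hit zero
    V[np.diag_indices_from(V)] += 1e-10
    try:
        cf = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return 1e12
    logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
    ones = np.ones(n)
    rhs = np.column_stack([y, ones])
    sol = cho_solve(cf, rhs, check_finite=False)
    Vi_y, Vi_1 = sol[:, 0], sol[:, 1]
    xvx = ones @ Vi_1
    quad = y @ Vi_y - (ones @ Vi_y) ** 2 / xvx
    return logdetV + np.log(xvx) + quad


def fit_mixed_model(p: PhenotypeTable, trait: str, regime: str) -> VarianceComponents:
    """REML variance components for one trait within one water regime.

    Single-year data degrade gracefully: ``sigma2_y`` and ``sigma2_gy`` are
    inestimable, returned as 0 with ``single_year=True`` and a warning.

    For ``regime="CWR"`` the model is fitted to regime-averaged plot data:
    each (genotype, year, block) cell is the mean of the WS and WW plot
    values, an approximation consistent with analysing the combined-regime
    line means.
    """
    if regime == CWR:
        df = (
            p.subset(trait=trait)
            .records.groupby(["genotype", "year", "block"], as_index=False)["value"]
            .mean()
        )
    else:
        df = p.subset(trait=trait, regime=regime).records
    y_raw = df["value"].to_numpy(dtype=float)
    n = len(y_raw)
    e_years = int(df["year"].nunique())
    r_reps = max(1, int(round(df.groupby("year")["block"].nunique().mean())))

    single_year = e_years < 2
    if single_year:
        warnings.warn(
            "single-year data: sigma2_y and sigma2_gy are inestimable, set to 0",
            stacklevel=2,
        )

    # scale to unit variance so the optimizer sees O(1) parameters; H2 is
    # invariant to this rescaling and estimates are mapped back at the end
    scale = y_raw.var()
    if scale == 0:
        return VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.0, e_years, r_reps,
                                  single_year=single_year)
    y = y_raw / np.sqrt(scale)

    Zg = _one_hot(df["genotype"])
    terms = [Zg @ Zg.T]
    names = ["sigma2_g"]
    if not single_year:
        Zy = _one_hot(df["year"])
        Zgy = _one_hot(df["genotype"].astype(str) + "\x1f" + df["year"].astype(str))
        terms += [Zy @ Zy.T, Zgy @ Zgy.T]
        names += ["sigma2_y", "sigma2_gy"]
    if df.groupby("year")["block"].nunique().max() > 1:
        Zb = _one_hot(df["year"].astype(str) + "\x1f" + df["block"].astype(str))
        terms.append(Zb @ Zb.T)
        names.append("sigma2_b")

    k = len(terms)
    x0 = np.full(k + 1, 1.0 / (k + 1))
    # warm start from method-of-moments on balanced data
    try:
        mom = _anova_from_df(df.assign(value=y))
        start = [max(1e-3, getattr(mom, nm)) for nm in names]
        start.append(max(1e-3, mom.sigma2_e))
        x0 = np.asarray(start)
    except ValueError:
        pass
    res = optimize.minimize(
        _reml_neg2ll,
        x0,
        args=(terms, y),
        method="L-BFGS-B",
        bounds=[(0.0, 50.0)] * (k + 1),
    )
    theta = np.asarray(res.x)
    theta[theta < 1e-8] = 0.0
    theta *= scale

    comp = dict.fromkeys(COMPONENT_NAMES, 0.0)
    for name, value in zip(names, theta[:-1]):
        comp[name] = float(value)
    comp["sigma2_e"] = float(theta[-1])
    return VarianceComponents(
        e_years=e_years,
        r_reps=r_reps,
        converged=bool(res.success),
        single_year=single_year,
        loglik=-0.5 * float(res.fun),
        **comp,
    )


def anova_components(p: PhenotypeTable, trait: str, regime: str) -> VarianceComponents:
    """Method-of-moments (expected-mean-squares) estimates on balanced data.

    Serves as an independent cross-check for :func:`fit_mixed_model`: on
    balanced data with all moment estimates non-negative, ANOVA and REML
    estimates agree.  Estimates are truncated at zero.
    """
    df = p.subset(trait=trait, regime=regime).records
    return _anova_from_df(df)


def _anova_from_df(df: pd.DataFrame) -> VarianceComponents:
    g = df["genotype"].nunique()
    e = df["year"].nunique()
    r = df.groupby("year")["block"].nunique().max()
    if len(df) != g * e * r:
        raise ValueError("anova_components requires a complete balanced table")

    grand = df["value"].mean()
    mg = df.groupby("genotype")["value"].mean()
    my = df.groupby("year")["value"].mean()
    mgy = df.groupby(["genotype", "year"])["value"].mean()
    myb = df.groupby(["year", "block"])["value"].mean()

    ss_g = e * r * ((mg - grand) ** 2).sum()
    ss_y = g * r * ((my - grand) ** 2).sum()
    inter = mgy - mg.reindex(mgy.index.get_level_values(0)).to_numpy() \
        - my.reindex(mgy.index.get_level_values(1)).to_numpy() + grand
    ss_gy = r * (inter ** 2).sum()
    ss_b = g * ((myb - my.reindex(myb.index.get_level_values(0)).to_numpy()) ** 2).sum()
    ss_tot = ((df["value"] - grand) ** 2).sum()
    ss_e = ss_tot - ss_g - ss_y - ss_gy - ss_b

    ms_g = ss_g / (g - 1)
    ms_gy = ss_gy / ((g - 1) * (e - 1)) if e > 1 else 0.0
    ms_y = ss_y / (e - 1) if e > 1 else 0.0
    ms_b = ss_b / (e * (r - 1)) if r > 1 else 0.0
    df_e = e * (r - 1) * (g - 1)
    ms_e = ss_e / df_e if df_e > 0 else 0.0

    s2_gy = max(0.0, (ms_gy - ms_e) / r) if e > 1 else 0.0
    s2_g = max(0.0, (ms_g - (ms_gy if e > 1 else ms_e)) / (e * r))
    s2_b = max(0.0, (ms_b - ms_e) / g) if r > 1 else 0.0
    s2_y = max(0.0, (ms_y - ms_gy - ms_b + ms_e) / (g * r)) if e > 1 else 0.0
    return VarianceComponents(s2_g, s2_y, s2_gy, s2_b, max(0.0, ms_e), e, r)


# ---------------------------------------------------------------------------
# Heritability and coefficients of variation
# ---------------------------------------------------------------------------


def heritability(v: VarianceComponents) -> float:
    """Broad-sense heritability H2 = s2_g / (s2_g + s2_gy/e + s2_e/(r*e))."""
    denom = v.sigma2_g + v.sigma2_gy / v.e_years + v.sigma2_e / (v.r_reps * v.e_years)
    if denom == 0:
        raise ValueError("all variance components are zero; H2 undefined")
    return v.sigma2_g / denom


def cv_coefficients(v: VarianceComponents, trait_mean: float):
    """(GCV, PCV, ECV) in percent of the trait mean.

    GV = sigma2_g, PV = the entry-mean H2 denominator, EV = sigma2_e;
    GCV = 100 sqrt(GV)/mean and likewise for PCV, ECV.
    """
    if trait_mean <= 0:
        raise ValueError("trait mean must be positive for coefficients of variation")
    gv = v.sigma2_g
    pv = v.sigma2_g + v.sigma2_gy / v.e_years + v.sigma2_e / (v.r_reps * v.e_years)
    ev = v.sigma2_e
    return (
        100.0 * np.sqrt(gv) / trait_mean,
        100.0 * np.sqrt(pv) / trait_mean,
        100.0 * np.sqrt(ev) / trait_mean,
    )


def trait_summary(p: PhenotypeTable, trait: str, regime: str) -> TraitSummary:
    """Mean, variability components and H2 for one trait x regime."""
    v = fit_mixed_model(p, trait, regime)
    means = p.line_means(trait, regime)
    gv = v.sigma2_g
    pv = v.sigma2_g + v.sigma2_gy / v.e_years + v.sigma2_e / (v.r_reps * v.e_years)
    ev = v.sigma2_e
    gcv, pcv, ecv = cv_coefficients(v, means.mean())
    return TraitSummary(
        trait=trait,
        regime=regime,
        mean=float(means.mean()),
        se=float(means.std(ddof=1) / np.sqrt(len(means))),
        range=(float(means.min()), float(means.max())),
        GV=gv,
        PV=pv,
        EV=ev,
        GCV=gcv,
        PCV=pcv,
        ECV=ecv,
        H2=heritability(v),
        components=v,
    )


def variance_table(p: PhenotypeTable, regimes=None, include_cwr: bool = True) -> pd.DataFrame:
    """Genetic-variability table (one row per trait x regime)."""
    regimes = list(regimes) if regimes is not None else list(p.regimes)
    if include_cwr and len(p.regimes) > 1:
        regimes = regimes + [CWR]
    rows = []
    for regime in regimes:
        for trait in p.traits:
            s = trait_summary(p, trait, regime)
            rows.append(
                {
                    "trait": trait, "regime": regime, "mean": s.mean, "se": s.se,
                    "min": s.range[0], "max": s.range[1], "GV": s.GV, "PV": s.PV,
                    "EV": s.EV, "GCV": s.GCV, "PCV": s.PCV, "ECV": s.ECV, "H2": s.H2,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trait correlations
# ---------------------------------------------------------------------------


def trait_correlations(p: PhenotypeTable, min_pairs: int = 3) -> dict:
    """Pearson correlations of line means within and across regimes.

    Returns a dict with one square trait x trait matrix per regime and, when
    two regimes are present, a ``"cross"`` matrix whose (i, j) entry is the
    correlation of trait i line means in the first regime with trait j line
    means in the second.  Cells with fewer than ``min_pairs`` complete pairs
    are NaN.  ``"n"`` holds the number of lines used.
    """
    out = {}
    frames = {r: p.line_mean_frame(r) for r in p.regimes}
    for regime, frame in frames.items():
        out[regime] = frame.corr(method="pearson", min_periods=min_pairs)
    if len(frames) == 2:
        r1, r2 = p.regimes
        f1, f2 = frames[r1].align(frames[r2], join="inner", axis=0)
        cross = pd.DataFrame(
            np.nan, index=f1.columns, columns=f2.columns, dtype=float
        )
        for a in f1.columns:
            for b in f2.columns:
                pair = pd.concat([f1[a], f2[b]], axis=1).dropna()
                if len(pair) >= min_pairs:
                    cross.loc[a, b] = pair.iloc[:, 0].corr(pair.iloc[:, 1])
        cross.index.name = r1
        cross.columns.name = r2
        out["cross"] = cross
    out["n"] = len(next(iter(frames.values())))
    return out
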