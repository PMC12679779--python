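"""Synthetic genotypes and multi-environment trial phenotypes.

The generator emulates the data structure of a wheat genomic-selection
study: a panel of inbred lines scored on a SNP array (dosages {0, 2} with
residual heterozygous calls and missing data), evaluated in randomized
complete blocks over multiple years under two water regimes (WS and WW).

Phenotypes are built generatively from the same mixed model the analysis
assumes:

    y_ikj = mu + g_i + y_k + (gy)_ik + b_j(k) + eps_ikj

with the genetic value ``g_i`` an additive function of marker dosages whose
per-marker effects are drawn from one of the prior families used by
whole-genome regression models (Gaussian, scaled-t, point-mass mixture,
Laplace).  Variance components are set by inverting the entry-mean
heritability formula so that the configured ``target_h2`` holds exactly at
the level of the true components; the WS and WW genetic values share a
configurable per-marker effect correlation ``regime_cor``.

Markers are independent by default; an optional AR(1) block-LD mode exists
so that nearest-neighbour imputation has signal to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from wheatgs.genotypes import GenotypeMatrix
from wheatgs.phenotypes import PhenotypeTable
from wheatgs.quantgen import VarianceComponents, heritability

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_effects",
           "simulate_trials", "EFFECT_MODELS", "REGIMES"]

EFFECT_MODELS = ("normal", "scaled_t", "point_mass_mixture", "laplace")
REGIMES = ("WS", "WW")


@dataclass
class SimConfig:
    """Study conditions for one simulated trait.

    Defaults mirror the real study's setting at desk scale: a ~180-line
    panel with array SNPs at MAF >= 0.05, two years x two blocks per water
    regime, a moderately heritable trait (``target_h2 = 0.69``, the
    thousand-kernel-weight value under water stress) and a strong
    cross-regime genetic correlation (``regime_cor = 0.84``, the observed
    WS/WW correlation of thousand kernel weight).
    """

    n_lines: int = 179
    n_markers: int = 2000
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.03
    het_rate: float = 0.01
    effect_model: str = "normal"
    pi_zero: float = 0.95
    target_h2: float = 0.69
    n_years: int = 2
    n_blocks: int = 2
    regime_cor: float = 0.84
    #: sizes of sigma2_y, sigma2_gy, sigma2_b relative to sigma2_g (= 1)
    variance_ratios: dict = field(
        default_factory=lambda: {"y": 1.0, "gy": 0.25, "b": 0.25}
    )
    mu: float = 40.0
    trait: str = "trait"
    t_df: float = 5.0
    #: markers per LD block; 1 = independent markers (default)
    ld_block_size: int = 1
    #: AR(1) latent correlation between adjacent markers within a block
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 10 or self.n_markers < 10:
            raise ValueError("need n_lines >= 10 and n_markers >= 10")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie inside (0, 0.5]")
        for name in ("missing_rate", "het_rate", "pi_zero"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0) and not (name == "pi_zero" and v == 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.pi_zero > 1.0:
            raise ValueError("pi_zero must be <= 1")
        if not (0.0 < self.target_h2 < 1.0):
            raise ValueError("target_h2 must be strictly inside (0, 1)")
        if self.effect_model not in EFFECT_MODELS:
            raise ValueError(f"effect_model must be one of {EFFECT_MODELS}")
        if not (-1.0 <= self.regime_cor <= 1.0):
            raise ValueError("regime_cor must be in [-1, 1]")
        if self.n_years < 1 or self.n_blocks < 1:
            raise ValueError("n_years and n_blocks must be >= 1")
        if self.ld_block_size < 1 or not (-1.0 < self.ld_rho < 1.0):
            raise ValueError("invalid LD settings")

    def component_values(self) -> dict:
        """True variance components implied by target_h2 and variance_ratios.

        sigma2_g is fixed at 1; sigma2_e is obtained by inverting
        H2 = s2_g / (s2_g + s2_gy/e + s2_e/(r e)) given the ratio-defined
        sigma2_gy.
        """
        s2_g = 1.0
        s2_y = float(self.variance_ratios.get("y", 0.0)) * s2_g
        s2_gy = float(self.variance_ratios.get("gy", 0.0)) * s2_g
        s2_b = float(self.variance_ratios.get("b", 0.0)) * s2_g
        e, r = self.n_years, self.n_blocks
        s2_e = r * e * (s2_g / self.target_h2 - s2_g - s2_gy / e)
        if s2_e < 0:
            raise ValueError(
                "target_h2 unattainable: genotype-by-year variance alone caps "
                f"H2 at {s2_g / (s2_g + s2_gy / e):.3f}"
            )
        return {"sigma2_g": s2_g, "sigma2_y": s2_y, "sigma2_gy": s2_gy,
                "sigma2_b": s2_b, "sigma2_e": s2_e}


@dataclass
class SimTruth:
    """Ground truth saved by :func:`simulate_trials` for recovery tests."""

    true_effects: dict          # regime -> per-marker effects (trait units)
    true_breeding_values: pd.DataFrame  # lines x regimes
    realized_h2: float
    component_values: dict


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None
                       ) -> GenotypeMatrix:
    """Simulate an inbred-line dosage matrix.

    Per-marker ALT-allele frequencies are uniform on ``cfg.maf_range``; each
    line carries dosage 2 with that probability, else 0 (inbred lines: no
    true heterozygotes).  Heterozygous artifacts (dosage 1) are then planted
    at ``het_rate`` among non-missing calls and calls are masked to missing
    at ``missing_rate``.  With ``ld_block_size > 1`` the underlying Bernoulli
    draws are coupled through a latent AR(1) Gaussian within blocks.

    The uncorrupted {0,2} matrix is attached to the result as ``.truth`` so
    phenotypes can be simulated on complete data.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, m = cfg.n_lines, cfg.n_markers
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)

    if cfg.ld_block_size > 1 and cfg.ld_rho != 0.0:
        z = np.empty((n, m))
        for start in range(0, m, cfg.ld_block_size):
            stop = min(start + cfg.ld_block_size, m)
            width = stop - start
            eps = rng.standard_normal((n, width))
            z[:, start] = eps[:, 0]
            for j in range(1, width):
                z[:, start + j] = (
                    cfg.ld_rho * z[:, start + j - 1]
                    + np.sqrt(1 - cfg.ld_rho**2) * eps[:, j]
                )
        u = stats.norm.cdf(z)
    else:
        u = rng.random((n, m))
    truth = np.where(u < freqs, 2.0, 0.0)

    dosages = truth.copy()
    miss = rng.random((n, m)) < cfg.missing_rate
    het = rng.random((n, m)) < cfg.het_rate
    dosages[het & ~miss] = 1.0
    dosages[miss] = np.nan

    line_ids = [f"L{i:04d}" for i in range(n)]
    marker_ids = [f"M{j:05d}" for j in range(m)]
    g = GenotypeMatrix(line_ids, marker_ids, dosages)
    g.truth = GenotypeMatrix(line_ids, marker_ids, truth)
    return g


# ---------------------------------------------------------------------------
# marker effects
# ---------------------------------------------------------------------------


def _raw_effects(model: str, m: int, cfg: SimConfig, rng: np.random.Generator
                 ) -> np.ndarray:
    """Unit-variance draws from the requested prior family."""
    if model == "normal":
        return rng.standard_normal(m)
    if model == "scaled_t":
        df = cfg.t_df
        return rng.standard_t(df, size=m) / np.sqrt(df / (df - 2.0))
    if model == "laplace":
        return rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=m)
    if model == "point_mass_mixture":
        eff = np.zeros(m)
        n_zero = int(np.floor(cfg.pi_zero * m))
        nonzero = rng.permutation(m)[: m - n_zero]
        eff[nonzero] = rng.standard_normal(len(nonzero))
        return eff
    raise ValueError(f"unknown effect model {model!r}")


def simulate_effects(cfg: SimConfig, markers: int,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-marker additive effects from the configured prior family.

    The vector is scaled so the expected additive genetic variance over a
    population with allele frequencies uniform on ``maf_range`` equals 1
    (i.e. sum_j 2 p_j (1-p_j) u_j^2 ~ 1); downstream simulation rescales
    genetic values to the exact target variance.
    """
    if cfg.pi_zero >= 1.0 and cfg.effect_model == "point_mass_mixture":
        return np.zeros(markers)
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    eff = _raw_effects(cfg.effect_model, markers, cfg, rng)
    lo, hi = cfg.maf_range
    # E[2p(1-p)] for p ~ U(lo, hi)
    mean_p = (lo + hi) / 2.0
    mean_p2 = (lo**2 + lo * hi + hi**2) / 3.0
    het_exp = 2.0 * (mean_p - mean_p2)
    nonzero = np.count_nonzero(eff)
    if nonzero:
        eff = eff / np.sqrt(nonzero * het_exp)
    return eff


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------


def simulate_trials(cfg: SimConfig, geno: GenotypeMatrix
                    ) -> tuple[PhenotypeTable, SimTruth]:
    """Simulate plot-level phenotypes for both water regimes.

    ``geno`` must be complete ({0,2} dosages, no missing); pass the
    ``.truth`` matrix attached by :func:`simulate_genotypes`.  Genetic
    values are rescaled to have population variance exactly ``sigma2_g``
    within each regime, so the realized heritability of the true components
    equals ``target_h2`` by construction.
    """
    truth = getattr(geno, "truth", geno)
    if truth.missing_mask.any():
        raise ValueError("simulate_trials needs the complete truth matrix")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    comp = cfg.component_values()
    n, m = truth.n_lines, truth.n_markers

    # correlated per-marker effects for the two regimes
    e1 = simulate_effects(cfg, m, rng)
    e2 = simulate_effects(cfg, m, rng)
    rho = cfg.regime_cor
    effects = {
        "WS": e1,
        "WW": rho * e1 + np.sqrt(max(0.0, 1.0 - rho**2)) * e2,
    }

    Xc = truth.dosages - truth.dosages.mean(axis=0)
    tbv = {}
    for regime in REGIMES:
        g_val = Xc @ effects[regime]
        sd = g_val.std()
        if sd == 0:
            raise ValueError("degenerate genetic values (all-zero effects or "
                             "monomorphic genotypes)")
        factor = np.sqrt(comp["sigma2_g"]) / sd
        g_val = g_val * factor
        effects[regime] = effects[regime] * factor
        tbv[regime] = g_val

    rows = []
    for regime in REGIMES:
        year_eff = rng.normal(0.0, np.sqrt(comp["sigma2_y"]), size=cfg.n_years)
        gy_eff = rng.normal(0.0, np.sqrt(comp["sigma2_gy"]),
                            size=(n, cfg.n_years))
        blk_eff = rng.normal(0.0, np.sqrt(comp["sigma2_b"]),
                             size=(cfg.n_years, cfg.n_blocks))
        resid = rng.normal(0.0, np.sqrt(comp["sigma2_e"]),
                           size=(n, cfg.n_years, cfg.n_blocks))
        for k in range(cfg.n_years):
            for j in range(cfg.n_blocks):
                vals = (cfg.mu + tbv[regime] + year_eff[k] + gy_eff[:, k]
                        + blk_eff[k, j] + resid[:, k, j])
                rows.append(pd.DataFrame({
                    "genotype": truth.line_ids,
                    "year": 2021 + k,
                    "block": j + 1,
                    "regime": regime,
                    "trait": cfg.trait,
                    "value": vals,
                }))
    table = PhenotypeTable(pd.concat(rows, ignore_index=True))

    vc = VarianceComponents(e_years=cfg.n_years, r_reps=cfg.n_blocks, **comp)
    truth_out = SimTruth(
        true_effects=effects,
        true_breeding_values=pd.DataFrame(tbv, index=truth.line_ids),
        realized_h2=heritability(vc),
        component_values=comp,
    )
    return table, truth_out


def simulate_study(cfg: SimConfig, traits: dict | None = None):
    """Simulate shared genotypes plus one or more traits.

    ``traits`` maps trait name -> dict of SimConfig overrides (e.g.
    ``{"TKW": {"target_h2": 0.69}, "GY": {"target_h2": 0.20}}``).  Returns
    ``(GenotypeMatrix, PhenotypeTable, {trait: SimTruth})``.
    """
    geno = simulate_genotypes(cfg)
    if not traits:
        traits = {cfg.trait: {}}
    tables, truths = [], {}
    for i, (name, overrides) in enumerate(sorted(traits.items())):
        tcfg = replace(cfg, trait=name, seed=cfg.seed + 1000 * (i + 1), **overrides)
        table, truth = simulate_trials(tcfg, geno.truth)
        tables.append(table.records)
        truths[name] = truth
    return geno, PhenotypeTable(pd.concat(tables, ignore_index=True)), truths
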