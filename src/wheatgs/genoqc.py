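"""Marker quality control and k-nearest-neighbour imputation.

The QC pipeline for an inbred-line SNP array, in fixed order:

1. heterozygous calls are masked to missing (inbred material; dosage-1
   calls are treated as artifacts — masked calls count toward missingness
   in the next step);
2. markers with more than the allowed fraction of missing calls are
   discarded (strictly "more than": a marker exactly at the threshold is
   retained);
3. markers with minor allele frequency below the threshold are discarded
   (MAF computed on the remaining non-missing calls);
4. remaining missing calls are imputed by k nearest neighbours over lines
   and rounded to the homozygous dosages {0, 2}.

A flag switches heterozygote handling from call-masking to whole-column
removal for users who read the rule the stricter way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.impute import KNNImputer

from wheatgs.genotypes import GenotypeMatrix

__all__ = ["QCConfig", "QCReport", "filter_maf", "filter_missing",
           "remove_heterozygotes", "knn_impute", "run_qc"]

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Thresholds of the QC pipeline (defaults: MAF 5%, 30% missing, K=5)."""

    maf_threshold: float = 0.05
    max_missing: float = 0.30
    knn_k: int = 5
    #: "mask" sets heterozygous calls to missing; "drop" removes the column
    het_mode: str = "mask"

    def __post_init__(self):
        if not (0.0 < self.maf_threshold < 0.5):
            raise ValueError("maf_threshold must be in (0, 0.5)")
        if not (0.0 < self.max_missing < 1.0):
            raise ValueError("max_missing must be in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.het_mode not in ("mask", "drop"):
            raise ValueError("het_mode must be 'mask' or 'drop'")


@dataclass
class QCReport:
    """Bookkeeping of one QC run."""

    n_input_markers: int = 0
    n_removed_maf: int = 0
    n_removed_missing: int = 0
    n_het_calls_removed: int = 0
    n_het_markers_dropped: int = 0
    n_imputed_cells: int = 0
    n_mode_fallback_markers: int = 0
    n_output_markers: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def remove_heterozygotes(g: GenotypeMatrix, mode: str = "mask",
                         report: QCReport | None = None) -> GenotypeMatrix:
    """Mask heterozygous (dosage 1) calls to missing, or drop their columns.

    The default masks calls only; no marker column is deleted by this step
    (columns badly affected become eligible for the missingness filter).
    """
    het = g.dosages == 1.0
    if not het.any():
        return g.copy()
    if mode == "drop":
        keep = ~het.any(axis=0)
        if report is not None:
            report.n_het_markers_dropped = int((~keep).sum())
        log.info("heterozygote removal: dropped %d marker columns", (~keep).sum())
        return g.select_markers(keep)
    out = g.copy()
    out.dosages[het] = np.nan
    if report is not None:
        report.n_het_calls_removed = int(het.sum())
    log.info("heterozygote removal: masked %d calls", het.sum())
    return out


def filter_missing(g: GenotypeMatrix, max_missing: float = 0.30,
                   report: QCReport | None = None) -> GenotypeMatrix:
    """Discard markers with strictly more than ``max_missing`` missing calls."""
    keep = g.missing_frac <= max_missing
    n_removed = int((~keep).sum())
    if report is not None:
        report.n_removed_missing = n_removed
    if n_removed:
        log.info("missingness filter (> %.0f%%): removed %d markers",
                 100 * max_missing, n_removed)
    return g.select_markers(keep)


def filter_maf(g: GenotypeMatrix, threshold: float = 0.05,
               report: QCReport | None = None) -> GenotypeMatrix:
    """Keep markers with MAF >= ``threshold`` (computed on non-missing calls)."""
    if not (0.0 < threshold < 0.5):
        raise ValueError("MAF threshold must be in (0, 0.5)")
    with np.errstate(invalid="ignore"):
        keep = g.maf >= threshold
    keep &= ~np.isnan(g.maf)  # markers with zero observed calls go too
    n_removed = int((~keep).sum())
    if report is not None:
        report.n_removed_maf = n_removed
    if n_removed:
        log.info("MAF filter (< %.2f): removed %d markers", threshold, n_removed)
    if keep.sum() == 0:
        log.warning("MAF filter removed every marker")
    return g.select_markers(keep)


def knn_impute(g: GenotypeMatrix, k: int = 5) -> GenotypeMatrix:
    """Impute missing dosages from the k nearest lines, rounding to {0, 2}.

    Distance between lines is Euclidean over mutually observed markers,
    scaled by the number of shared markers (scikit-learn's nan-Euclidean);
    the k neighbours contribute with uniform weights.  Markers where fewer
    than k lines have observed calls fall back to the marker mode (logged).
    Observed cells are returned bit-exactly unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    miss = g.missing_mask
    if not miss.any():
        return g.copy()

    out = g.copy()
    n_obs = (~miss).sum(axis=0)
    thin = n_obs <= k  # too few donors: nearest-neighbour set would include self-column info
    if thin.any():
        log.warning("kNN imputation: %d markers with <= %d observed calls "
                    "fall back to marker mode", int(thin.sum()), k)
        for j in np.flatnonzero(thin):
            col = out.dosages[:, j]
            observed = col[~np.isnan(col)]
            if observed.size == 0:
                mode = 0.0
            else:
                vals, counts = np.unique(observed, return_counts=True)
                mode = vals[np.argmax(counts)]
            col[np.isnan(col)] = mode

    still = np.isnan(out.dosages)
    if still.any():
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        filled = imputer.fit_transform(out.dosages)
        if filled.shape[1] != out.n_markers:  # all-NaN columns (none expected after filters)
            raise RuntimeError("imputer dropped all-missing marker columns; "
                               "run the missingness filter first")
        out.dosages[still] = filled[still]
    # round to the nearest homozygous dosage
    out.dosages[miss] = np.where(out.dosages[miss] < 1.0, 0.0, 2.0)

    report_cells = int(miss.sum())
    log.info("kNN imputation (k=%d): filled %d cells", k, report_cells)
    return out


def run_qc(g: GenotypeMatrix, cfg: QCConfig | None = None
           ) -> tuple[GenotypeMatrix, QCReport]:
    """Full pipeline: het handling -> missingness filter -> MAF filter -> kNN.

    Returns the cleaned, fully imputed matrix and a :class:`QCReport` whose
    counts satisfy ``n_output_markers = n_input_markers - n_removed_maf -
    n_removed_missing - n_het_markers_dropped``.
    """
    cfg = cfg or QCConfig()
    report = QCReport(n_input_markers=g.n_markers)
    g1 = remove_heterozygotes(g, mode=cfg.het_mode, report=report)
    g2 = filter_missing(g1, cfg.max_missing, report=report)
    g3 = filter_maf(g2, cfg.maf_threshold, report=report)
    report.n_imputed_cells = int(g3.missing_mask.sum())
    n_obs = (~g3.missing_mask).sum(axis=0)
    report.n_mode_fallback_markers = int((n_obs <= cfg.knn_k).sum())
    g4 = knn_impute(g3, cfg.knn_k)
    report.n_output_markers = g4.n_markers
    return g4, report
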