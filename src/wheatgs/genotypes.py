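"""Dosage-matrix container for biallelic SNP genotypes of inbred lines.

Genotypes are stored as a dense float matrix of allele dosages, lines in
rows and markers in columns, with values in {0, 1, 2} and ``NaN`` marking
missing calls.  Dosage 1 (a heterozygous call) is expected only as an
artifact in inbred material and is masked out during QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix"]

_VALID_DOSAGES = (0.0, 1.0, 2.0)


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with a missingness mask.

    Parameters
    ----------
    line_ids : sequence of str
        Unique identifiers of the lines (rows).
    marker_ids : sequence of str
        Unique identifiers of the markers (columns).
    dosages : ndarray of float, shape (n_lines, n_markers)
        Allele dosages in {0, 1, 2}; ``NaN`` encodes a missing call.
    """

    line_ids: list = field(default_factory=list)
    marker_ids: list = field(default_factory=list)
    dosages: np.ndarray = None

    def __post_init__(self):
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D lines x markers array")
        n, m = self.dosages.shape
        if len(self.line_ids) != n:
            raise ValueError(f"{len(self.line_ids)} line ids for {n} rows")
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, _VALID_DOSAGES).all():
            bad = np.unique(obs[~np.isin(obs, _VALID_DOSAGES)])
            raise ValueError(f"dosages outside {{0,1,2}}: {bad}")

    # -- basic geometry -------------------------------------------------

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the call is missing."""
        return np.isnan(self.dosages)

    # -- derived per-marker statistics ----------------------------------

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of the counted (ALT) allele on non-missing calls.

        Lines are treated as diploid: each call contributes two alleles,
        so a heterozygous call contributes one of each.  Markers with no
        observed calls get ``NaN``.
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency in [0, 0.5]."""
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    @property
    def missing_frac(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return self.missing_mask.mean(axis=0)

    # -- manipulation ---------------------------------------------------

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.line_ids), list(self.marker_ids), self.dosages.copy())

    def select_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to markers where ``keep`` is True
        (boolean mask) or to the given integer indices."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            list(self.line_ids),
            [self.marker_ids[i] for i in idx],
            self.dosages[:, idx].copy(),
        )

    def centred(self) -> np.ndarray:
        """Column-centred dosage matrix (requires no missing calls)."""
        if self.missing_mask.any():
            raise ValueError("centring requires a complete (imputed) matrix")
        return self.dosages - self.dosages.mean(axis=0)

    def standardized(self, drop_monomorphic: bool = True):
        """Column-standardized dosages (mean 0, unit variance per marker).

        Returns ``(X, kept_marker_ids)``.  Zero-variance columns cannot be
        standardized and are dropped when ``drop_monomorphic`` is set,
        otherwise an error is raised.
        """
        if self.missing_mask.any():
            raise ValueError("standardization requires a complete matrix")
        sd = self.dosages.std(axis=0)
        keep = sd > 0
        if not drop_monomorphic and not keep.all():
            raise ValueError("zero-variance marker columns present")
        X = self.dosages[:, keep]
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        return X, [m for m, k in zip(self.marker_ids, keep) if k]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        miss = float(self.missing_mask.mean()) if self.dosages.size else 0.0
        return (
            f"GenotypeMatrix({self.n_lines} lines x {self.n_markers} markers, "
            f"{100 * miss:.1f}% missing)"
        )
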