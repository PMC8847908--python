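"""Build binary functional-connectivity graphs from ROI time series.

One subject's preprocessed T x R signal matrix is turned into a Pearson
correlation matrix, negative correlations are zeroed (positive-edge
networks only), and the matrix is binarized at each sparsity level of a
threshold sweep.  Sparsity ``S`` is the fraction of retained edges out of
the ``R(R-1)/2`` possible undirected pairs, so every subject's graph at a
given ``S`` has the same edge count regardless of overall correlation
strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "CorrelationMatrix",
    "BinaryGraphStack",
    "compute_correlation",
    "zero_negatives",
    "fisher_z",
    "target_edges",
    "binarize_at_sparsity",
    "threshold_sweep",
]


@dataclass
class RoiTimeSeries:
    """One subject's regional mean time series (rows = timepoints)."""

    subject_id: str
    data: np.ndarray  # T x R
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D (T x R) array")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.data.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.roi_labels)} ROI labels"
            )
        if not np.all(np.isfinite(self.data)):
            t, r = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite value for subject {self.subject_id!r} at "
                f"timepoint {t}, ROI {self.roi_labels[r]!r}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class CorrelationMatrix:
    """Symmetric R x R matrix of inter-regional correlations, diagonal 1."""

    values: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric (tol 1e-12)")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryGraphStack:
    """Boolean adjacency tensor over a sparsity grid for one subject.

    ``adjacency[:, :, k]`` is the binary graph at sparsity ``sparsity_grid[k]``.
    Slices are thresholded independently, so they need not be nested.
    """

    adjacency: np.ndarray  # R x R x n_S, bool
    sparsity_grid: np.ndarray
    roi_labels: list[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_levels(self) -> int:
        return self.adjacency.shape[2]

    def slice_at(self, k: int) -> np.ndarray:
        return self.adjacency[:, :, k]


def compute_correlation(ts: RoiTimeSeries) -> CorrelationMatrix:
    """Pairwise Pearson correlations of the ROI columns.

    Raises if any column is constant, naming the offending ROI.
    """
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.roi_labels[i] for i in dead)
        raise ValueError(f"zero-variance ROI column(s): {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    # corrcoef can wander a hair outside [-1, 1] in float arithmetic
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return CorrelationMatrix(values=r, roi_labels=list(ts.roi_labels))


def zero_negatives(corr: CorrelationMatrix) -> CorrelationMatrix:
    """Zero negative off-diagonal correlations; keep positive edges only."""
    v = corr.values.copy()
    off = ~np.eye(v.shape[0], dtype=bool)
    v[off] = np.maximum(v[off], 0.0)
    return CorrelationMatrix(values=v, roi_labels=list(corr.roi_labels))


def absolute_values(corr: CorrelationMatrix) -> CorrelationMatrix:
    """Alternative negative-edge handling: take absolute correlations."""
    v = np.abs(corr.values)
    np.fill_diagonal(v, 1.0)
    return CorrelationMatrix(values=v, roi_labels=list(corr.roi_labels))


def fisher_z(corr: CorrelationMatrix) -> np.ndarray:
    """Fisher r-to-z transform of the off-diagonal; diagonal set to 0."""
    v = corr.values
    off = ~np.eye(v.shape[0], dtype=bool)
    if np.any(np.abs(v[off]) >= 1.0):
        raise ValueError("|r| = 1 off-diagonal: Fisher z undefined")
    z = np.zeros_like(v)
    z[off] = np.arctanh(v[off])
    return z


def target_edges(S: float, n_rois: int) -> int:
    """Edge count implied by sparsity S: round(S * R(R-1)/2), half away from zero."""
    x = S * n_rois * (n_rois - 1) / 2.0
    return int(np.floor(x + 0.5))


def binarize_at_sparsity(
    corr: CorrelationMatrix, S: float, warn_list: list[str] | None = None
) -> np.ndarray:
    """Keep the ``target_edges(S)`` strongest positive pairs as edges.

    Ties in correlation value are broken by (i, j) lexicographic order so
    the result is deterministic.  If fewer strictly positive pairs exist
    than the target, the edge count is clamped and a warning recorded.
    """
    if not 0.0 < S < 1.0:
        raise ValueError(f"sparsity must be in (0, 1), got {S}")
    R = corr.n_rois
    iu, ju = np.triu_indices(R, k=1)
    vals = corr.values[iu, ju]
    if np.any(vals < 0):
        raise ValueError("binarization expects nonnegative off-diagonal values")
    want = target_edges(S, R)
    positive = vals > 0
    n_avail = int(positive.sum())
    take = min(want, n_avail)
    if take < want:
        msg = (
            f"S={S:g}: only {n_avail} positive pairs available for "
            f"{want} requested edges; clamped"
        )
        if warn_list is not None:
            warn_list.append(msg)
        warnings.warn(msg, stacklevel=2)
    adj = np.zeros((R, R), dtype=bool)
    if take > 0:
        # sort by value descending, then (i, j) ascending
        order = np.lexsort((ju, iu, -vals))
        order = order[positive[order]][:take]
        adj[iu[order], ju[order]] = True
        adj |= adj.T
    return adj


def sparsity_grid(s_min: float, s_max: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid s_min, s_min+step, ..., s_max (tol 1e-9)."""
    if not s_min < s_max:
        raise ValueError("require S_min < S_max")
    if step <= 0:
        raise ValueError("step must be positive")
    k = int(np.floor((s_max - s_min) / step + 1e-9))
    grid = s_min + step * np.arange(k + 1)
    if grid.size < 2:
        raise ValueError("sparsity grid must contain at least 2 points (AUC undefined)")
    return grid


def threshold_sweep(
    corr: CorrelationMatrix,
    s_min: float = 0.10,
    s_max: float = 0.30,
    step: float = 0.01,
) -> BinaryGraphStack:
    """Binarize at every sparsity level of the grid (default 0.10..0.30 by 0.01)."""
    grid = sparsity_grid(s_min, s_max, step)
    R = corr.n_rois
    warn_list: list[str] = []
    adj = np.zeros((R, R, grid.size), dtype=bool)
    for k, S in enumerate(grid):
        adj[:, :, k] = binarize_at_sparsity(corr, float(S), warn_list)
    return BinaryGraphStack(
        adjacency=adj,
        sparsity_grid=grid,
        roi_labels=list(corr.roi_labels),
        warnings=warn_list,
    )
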