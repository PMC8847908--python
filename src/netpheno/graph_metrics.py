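"""Nodal graph metrics on binary undirected graphs and their AUC summaries.

Two nodal metrics are computed at every sparsity level: the degree K_i
(number of direct neighbours) and the nodal global efficiency

    E_i_global = (1 / (N - 1)) * sum_{j != i} 1 / d(i, j),

the inverse harmonic mean of shortest-path lengths from node i, where an
unreachable node j contributes 0 (the limit 1/inf).  Each metric's
threshold profile is then integrated over the sparsity grid with the
composite trapezoid rule, giving one AUC value per node per metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistanceMatrix",
    "NodalMetricsAUC",
    "nodal_degree",
    "shortest_paths",
    "nodal_global_efficiency",
    "metric_auc",
    "subject_metrics",
]


@dataclass
class DistanceMatrix:
    """All-pairs unweighted shortest-path lengths; np.inf for unreachable."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.lengths, dtype=float)
        if not np.allclose(np.diag(L), 0):
            raise ValueError("distance matrix diagonal must be 0")
        self.lengths = L


@dataclass
class NodalMetricsAUC:
    """Per-node AUC of degree and global efficiency over the sparsity grid."""

    subject_id: str
    degree_auc: np.ndarray
    efficiency_auc: np.ndarray
    sparsity_grid: np.ndarray
    degree_per_threshold: np.ndarray | None = None  # R x n_S
    efficiency_per_threshold: np.ndarray | None = None

    @property
    def n_rois(self) -> int:
        return self.degree_auc.shape[0]


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.dtype != bool:
        adj = adj.astype(bool)
    if adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(np.diag(adj)):
        raise ValueError("adjacency diagonal must be zero (no self-loops)")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric (undirected graph)")
    return adj


def nodal_degree(adj: np.ndarray) -> np.ndarray:
    """Degree K_i: row sums of the boolean adjacency matrix."""
    adj = _check_adjacency(adj)
    return adj.sum(axis=1).astype(np.int64)


def shortest_paths(adj: np.ndarray) -> DistanceMatrix:
    """All-pairs shortest-path lengths by simultaneous breadth-first search.

    All sources are expanded one BFS level at a time using boolean
    matrix products; unreachable pairs get np.inf.
    """
    adj = _check_adjacency(adj)
    R = adj.shape[0]
    lengths = np.full((R, R), np.inf)
    np.fill_diagonal(lengths, 0.0)
    reached = np.eye(R, dtype=bool)  # nodes settled so far, per source row
    frontier = np.eye(R, dtype=bool)
    for d in range(1, R):
        # expand every source's frontier one hop
        frontier = (frontier @ adj) & ~reached
        if not frontier.any():
            break
        lengths[frontier] = d
        reached |= frontier
    return DistanceMatrix(lengths=lengths)


def nodal_global_efficiency(
    adj: np.ndarray, distances: DistanceMatrix | None = None
) -> np.ndarray:
    """E_i_global for every node; entries lie in [0, 1].

    A precomputed distance matrix may be passed to avoid repeating BFS.
    """
    adj = _check_adjacency(adj)
    R = adj.shape[0]
    if R < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    L = distances.lengths if distances is not None else shortest_paths(adj).lengths
    with np.errstate(divide="ignore"):
        inv = 1.0 / L
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (R - 1)


def metric_auc(per_threshold: np.ndarray, sparsity_grid: np.ndarray) -> np.ndarray:
    """Composite trapezoid integral of each node's metric profile over S."""
    per_threshold = np.asarray(per_threshold, dtype=float)
    grid = np.asarray(sparsity_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("sparsity grid must be 1-D with at least 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be strictly increasing")
    if per_threshold.ndim != 2 or per_threshold.shape[1] != grid.size:
        raise ValueError(
            f"per-threshold values shaped {per_threshold.shape} do not match "
            f"grid of length {grid.size}"
        )
    return np.trapezoid(per_threshold, grid, axis=1)


def subject_metrics(stack, keep_per_threshold: bool = False, subject_id: str | None = None):
    """Degree and efficiency at every sparsity level, integrated to AUC.

    Parameters
    ----------
    stack : BinaryGraphStack
        One subject's thresholded graphs.
    keep_per_threshold : bool
        Retain the full R x n_S metric matrices alongside the AUCs.
    """
    R, n_S = stack.n_rois, stack.n_levels
    deg = np.empty((R, n_S))
    eff = np.empty((R, n_S))
    for k in range(n_S):
        adj = stack.slice_at(k)
        deg[:, k] = nodal_degree(adj)
        eff[:, k] = nodal_global_efficiency(adj)
    sid = subject_id if subject_id is not None else getattr(stack, "subject_id", "")
    return NodalMetricsAUC(
        subject_id=sid,
        degree_auc=metric_auc(deg, stack.sparsity_grid),
        efficiency_auc=metric_auc(eff, stack.sparsity_grid),
        sparsity_grid=np.asarray(stack.sparsity_grid, dtype=float),
        degree_per_threshold=deg if keep_per_threshold else None,
        efficiency_per_threshold=eff if keep_per_threshold else None,
    )
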