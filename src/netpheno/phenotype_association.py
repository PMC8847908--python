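"""Covariate-adjusted association of network features with the AHS score.

The Analysis–Holism Scale (AHS) score is related to nodal metrics and to
node-level functional connectivity via partial correlation: both
variables are residualized on the covariates (sex, age, head motion by
default) with ordinary least squares and the residuals are correlated;
the p-value comes from the t distribution with n - 2 - k degrees of
freedom.  Benjamini–Hochberg FDR is applied within each screen.

Subjects with a missing AHS score are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .group_inference import fdr_bh
from .network_construction import RoiTimeSeries

__all__ = [
    "partial_correlation",
    "metric_ahs_screen",
    "node_fc_ahs_screen",
    "AssociationResult",
]

logger = logging.getLogger(__name__)

ASSOCIATION_COVARIATES = ("sex", "age", "motion")


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    beta = np.linalg.lstsq(C, v, rcond=None)[0]
    return v - C @ beta


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Correlation of x and y after removing covariates from both.

    ``covariates`` is an n x k matrix (an intercept is always included);
    with no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if covariates is None:
        C = np.ones((n, 1))
        k = 0
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        k = C.shape[1] - 1
    if n <= k + 2:
        raise ValueError(f"need more than {k + 2} observations for {k} covariates")
    rx = _residualize(x, C)
    ry = _residualize(y, C)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant residuals; partial correlation undefined")
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


@dataclass
class AssociationResult:
    """Per-item partial correlations with the AHS plus the FDR selection."""

    table: pd.DataFrame
    selected: list[tuple[str, str, int]]  # (roi, metric, sign)


def _ahs_subset(phenotypes: pd.DataFrame, covariates: tuple[str, ...]):
    """Row mask and covariate matrix for subjects with an AHS score."""
    has = phenotypes["ahs"].notna().to_numpy()
    n_drop = int((~has).sum())
    if n_drop:
        logger.info("dropping %d subjects without AHS score", n_drop)
    C = phenotypes.loc[has, list(covariates)].to_numpy(dtype=float)
    y = phenotypes.loc[has, "ahs"].to_numpy(dtype=float)
    return has, C, y


def metric_ahs_screen(
    degree_auc: np.ndarray,
    efficiency_auc: np.ndarray,
    roi_labels: list[str],
    phenotypes: pd.DataFrame,
    nodes: list[str] | None = None,
    covariates: tuple[str, ...] = ASSOCIATION_COVARIATES,
    q_level: float = 0.05,
) -> AssociationResult:
    """Partial correlation of AHS with each (node, metric) pair.

    ``nodes`` restricts the screen (typically to the consistent nodes of
    the group analysis); BH correction spans all tested metrics jointly.
    """
    if nodes is None:
        nodes = list(roi_labels)
    missing = [n for n in nodes if n not in roi_labels]
    if missing:
        raise ValueError(f"unknown nodes: {missing}")
    has, C, y = _ahs_subset(phenotypes, covariates)
    D = np.asarray(degree_auc, dtype=float)[has]
    Eff = np.asarray(efficiency_auc, dtype=float)[has]
    rows = []
    for roi in nodes:
        j = roi_labels.index(roi)
        for metric, M in (("degree_auc", D), ("efficiency_auc", Eff)):
            r, p = partial_correlation(M[:, j], y, C)
            rows.append(
                {
                    "roi": roi,
                    "metric": metric,
                    "r_partial": r,
                    "p": p,
                    "n_effective": int(has.sum()),
                }
            )
    table = pd.DataFrame(rows)
    rejected, q = fdr_bh(table["p"].to_numpy(), q_level)
    table["q"] = q
    table["significant"] = rejected
    selected = [
        (row.roi, row.metric, 1 if row.r_partial > 0 else -1)
        for row in table.itertuples()
        if row.significant
    ]
    return AssociationResult(table=table, selected=selected)


def pairwise_fc(
    ts: RoiTimeSeries, seed_label: str, use_fisher_z: bool = False
) -> np.ndarray:
    """Functional connectivity of one seed node with every other node."""
    j = ts.roi_labels.index(seed_label)
    x = ts.data[:, j]
    x = (x - x.mean()) / x.std()
    Z = (ts.data - ts.data.mean(axis=0)) / ts.data.std(axis=0)
    r = Z.T @ x / ts.n_timepoints
    r = np.clip(np.delete(r, j), -1.0, 1.0)
    if use_fisher_z:
        r = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    return r


def node_fc_ahs_screen(
    seed_label: str,
    timeseries: list[RoiTimeSeries],
    phenotypes: pd.DataFrame,
    covariates: tuple[str, ...] = ASSOCIATION_COVARIATES,
    q_level: float = 0.05,
    use_fisher_z: bool = False,
) -> AssociationResult:
    """Partial correlation of AHS with the seed node's FC to each other node.

    The FDR family spans exactly the R - 1 seed-to-target tests.
    """
    labels = timeseries[0].roi_labels
    if seed_label not in labels:
        raise ValueError(f"unknown seed node {seed_label!r}")
    order = {ts.subject_id: ts for ts in timeseries}
    ids = phenotypes["subject_id"].tolist()
    fc = np.array(
        [pairwise_fc(order[sid], seed_label, use_fisher_z) for sid in ids]
    )
    has, C, y = _ahs_subset(phenotypes, covariates)
    fc = fc[has]
    targets = [l for l in labels if l != seed_label]
    rows = []
    for t_idx, target in enumerate(targets):
        r, p = partial_correlation(fc[:, t_idx], y, C)
        rows.append(
            {
                "roi": f"{seed_label}--{target}",
                "metric": "fc",
                "r_partial": r,
                "p": p,
                "n_effective": int(has.sum()),
            }
        )
    table = pd.DataFrame(rows)
    rejected, q = fdr_bh(table["p"].to_numpy(), q_level)
    table["q"] = q
    table["significant"] = rejected
    selected = [
        (row.roi, "fc", 1 if row.r_partial > 0 else -1)
        for row in table.itertuples()
        if row.significant
    ]
    return AssociationResult(table=table, selected=selected)
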