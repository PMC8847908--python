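"""Node-wise group screening with covariate adjustment and FDR.

Every node is tested for a group difference in its (degree-AUC,
efficiency-AUC) pair with a multivariate analysis of covariance
(MANCOVA, Pillai's trace with the standard F approximation) and in each
metric separately with an ANCOVA (linear model ``metric ~ group +
covariates``).  Benjamini–Hochberg FDR control is applied across nodes,
separately per test family.  Nodes significant after FDR in the MANCOVA
and in *both* ANCOVAs are the "consistent" nodes passed downstream.

Directions are coded from the group-1-minus-group-0 adjusted difference:
``W`` when group 0 (Western) is higher, ``E`` when group 1 (Chinese/
Eastern) is higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "build_design",
    "ancova_node",
    "mancova_node",
    "fdr_bh",
    "screen_nodes",
    "ScreenResult",
]

DEFAULT_COVARIATES = ("age", "sex", "motion", "site")
#: covariates entered as categorical indicator columns
CATEGORICAL_COVARIATES = {"sex", "site"}


def build_design(
    phenotypes: pd.DataFrame, covariates: tuple[str, ...] = DEFAULT_COVARIATES
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Full and reduced (no-group) design matrices for the node tests.

    Categorical covariates become drop-first indicators; continuous ones
    are standardized for conditioning.  Returns (X_full, X_reduced,
    column names of X_full); the group column is always index 1.
    """
    n = len(phenotypes)
    groups = phenotypes["group"].to_numpy()
    if not set(np.unique(groups)) <= {0, 1}:
        raise ValueError("group must be coded 0/1")
    cols: list[np.ndarray] = [np.ones(n), groups.astype(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        if cov not in phenotypes.columns:
            raise ValueError(f"covariate column {cov!r} missing from phenotypes")
        x = phenotypes[cov]
        if x.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values")
        if cov in CATEGORICAL_COVARIATES:
            dummies = pd.get_dummies(x, prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(str(c))
        else:
            v = x.to_numpy(dtype=float)
            sd = v.std()
            cols.append((v - v.mean()) / sd if sd > 0 else np.zeros(n))
            names.append(cov)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    X_reduced = np.delete(X, 1, axis=1)
    return X, X_reduced, names


def _sse(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y after projecting on X."""
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    return np.einsum("ij,ij->j", resid, resid)


def _residuals(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Y - Q @ (Q.T @ Y)


def ancova_node(
    metric: np.ndarray,
    phenotypes: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> tuple[float, float, float, str]:
    """Covariate-adjusted group F test for one nodal metric.

    Returns (F, p, partial eta^2, direction).  With a constant metric the
    test is undefined and (nan, nan, nan, '·') is returned.
    """
    y = np.asarray(metric, dtype=float)
    X, X_red, _ = build_design(phenotypes, covariates)
    if len(y) != X.shape[0]:
        raise ValueError("metric length does not match phenotype rows")
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few subjects for the requested design")
    Y = y[:, None]
    sse_full = float(_sse(X, Y)[0])
    sse_red = float(_sse(X_red, Y)[0])
    df_e = len(y) - X.shape[1]
    if sse_full <= 0 or np.var(y) == 0:
        return (np.nan, np.nan, np.nan, "·")
    ss_group = max(sse_red - sse_full, 0.0)
    F = (ss_group / 1.0) / (sse_full / df_e)
    p = float(stats.f.sf(F, 1, df_e))
    eta_p2 = ss_group / (ss_group + sse_full)
    beta = np.linalg.lstsq(X, y, rcond=None)[0][1]
    direction = "E" if beta > 0 else "W"
    return (float(F), p, float(eta_p2), direction)


def mancova_node(
    degree_auc: np.ndarray,
    efficiency_auc: np.ndarray,
    phenotypes: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> tuple[float, float, float]:
    """Multivariate (Pillai's trace) group test on the metric pair.

    The group effect has one degree of freedom, so Pillai's V converts
    exactly to F = [V/(1-V)] * (df_e - p + 1)/p with df1 = p and
    df2 = df_e - p + 1, p = 2 dependent variables.
    """
    Y = np.column_stack(
        [np.asarray(degree_auc, dtype=float), np.asarray(efficiency_auc, dtype=float)]
    )
    X, X_red, _ = build_design(phenotypes, covariates)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("metric length does not match phenotype rows")
    R_full = _residuals(X, Y)
    R_red = _residuals(X_red, Y)
    E = R_full.T @ R_full
    H = R_red.T @ R_red - E
    p_dv = Y.shape[1]
    df_e = Y.shape[0] - X.shape[1]
    try:
        V = float(np.trace(H @ np.linalg.inv(H + E)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular residual cross-product; dependent variables collinear"
        ) from exc
    cond = np.linalg.cond(H + E)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "singular residual cross-product; dependent variables collinear"
        )
    V = min(max(V, 0.0), 1.0 - 1e-15)
    df1 = p_dv
    df2 = df_e - p_dv + 1
    F = (V / (1.0 - V)) * (df2 / df1)
    p = float(stats.f.sf(F, df1, df2))
    return (float(F), p, V)


def fdr_bh(pvalues: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (rejected mask, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return rejected, adjusted


@dataclass
class ScreenResult:
    """Node-wise statistics table plus the consistent-node selection."""

    table: pd.DataFrame
    consistent_nodes: list[str]


def screen_nodes(
    degree_auc: np.ndarray,
    efficiency_auc: np.ndarray,
    phenotypes: pd.DataFrame,
    roi_labels: list[str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    q_level: float = 0.05,
    fdr_families: str = "three",
) -> ScreenResult:
    """MANCOVA + both ANCOVAs for every node, FDR per family.

    Parameters
    ----------
    degree_auc, efficiency_auc : arrays, subjects x nodes
    fdr_families : "three" corrects MANCOVA, degree-ANCOVA and
        efficiency-ANCOVA each across nodes; "joint-ancova" pools the two
        ANCOVA families into one.
    """
    D = np.asarray(degree_auc, dtype=float)
    Eff = np.asarray(efficiency_auc, dtype=float)
    n_sub, R = D.shape
    if Eff.shape != (n_sub, R) or len(roi_labels) != R:
        raise ValueError("metric matrices and ROI labels are inconsistent")
    X, X_red, _ = build_design(phenotypes, covariates)
    df_e = n_sub - X.shape[1]

    # vectorized ANCOVAs across nodes
    def family(Y: np.ndarray):
        sse_full = _sse(X, Y)
        sse_red = _sse(X_red, Y)
        ss_group = np.maximum(sse_red - sse_full, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ss_group / (sse_full / df_e)
            eta = ss_group / (ss_group + sse_full)
        p = stats.f.sf(F, 1, df_e)
        beta = np.linalg.lstsq(X, Y, rcond=None)[0][1]
        return F, p, eta, beta

    F_d, p_d, eta_d, beta_d = family(D)
    F_e, p_e, eta_e, beta_e = family(Eff)
    man = [mancova_node(D[:, j], Eff[:, j], phenotypes, covariates) for j in range(R)]
    F_m = np.array([m[0] for m in man])
    p_m = np.array([m[1] for m in man])
    eta_m = np.array([m[2] for m in man])

    _, q_m = fdr_bh(p_m, q_level)
    if fdr_families == "three":
        _, q_d = fdr_bh(p_d, q_level)
        _, q_e = fdr_bh(p_e, q_level)
    elif fdr_families == "joint-ancova":
        _, q_joint = fdr_bh(np.concatenate([p_d, p_e]), q_level)
        q_d, q_e = q_joint[:R], q_joint[R:]
    else:
        raise ValueError(f"unknown fdr_families mode {fdr_families!r}")

    def directions(beta: np.ndarray, q: np.ndarray) -> list[str]:
        return [
            ("E" if b > 0 else "W") if qv < q_level else "·"
            for b, qv in zip(beta, q)
        ]

    table = pd.DataFrame(
        {
            "roi": roi_labels,
            "F_mancova": F_m,
            "p_mancova": p_m,
            "q_mancova": q_m,
            "eta_p2_mancova": eta_m,
            "F_deg": F_d,
            "p_deg": p_d,
            "q_deg": q_d,
            "eta_p2_deg": eta_d,
            "direction_deg": directions(beta_d, q_d),
            "F_eff": F_e,
            "p_eff": p_e,
            "q_eff": q_e,
            "eta_p2_eff": eta_e,
            "direction_eff": directions(beta_e, q_e),
        }
    )
    consistent_mask = (q_m < q_level) & (q_d < q_level) & (q_e < q_level)
    consistent = [roi_labels[j] for j in np.flatnonzero(consistent_mask)]
    return ScreenResult(table=table, consistent_nodes=consistent)
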