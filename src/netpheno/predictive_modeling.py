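"""Composite predictors, cross-validated prediction, and permutation nulls.

The association screen yields a set of nodal metrics with signed AHS
correlations.  Negatively associated metrics are sign-flipped
("direction unification"), degree metrics are averaged into T_deg and
efficiency metrics into T_eg, and the two composites enter either

* a 10-fold cross-validated ordinary-least-squares regression of the
  AHS score (estimate = Pearson r between out-of-fold predictions and
  observations), or
* a 10-fold cross-validated logistic regression of group membership
  (estimate = overall accuracy at a 0.5 probability cutoff).

Significance is calibrated by permuting the outcome across subjects and
rerunning the full cross-validation, recording the values at the sorted
25th and 975th positions of 1000 null estimates as the 95% interval.

The connectome-based predictive modeling (CPM) variant drops the prior
node selection: within every training fold each nodal metric is screened
by its zero-order correlation with the score (p < alpha), composites are
rebuilt fold-by-fold, and metrics selected in all 10 folds define the
stable set used for cross-sample classification.

By default direction unification and member selection are fixed on the
full sample before cross-validation, the convention this analysis
lineage uses; that leaks selection information into the folds, and
``leakage_free`` variants (the CPM path) re-estimate everything within
folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "CompositePredictors",
    "PredictionOutcome",
    "metric_table",
    "unify_directions",
    "build_composites",
    "kfold_predict_continuous",
    "kfold_classify",
    "permutation_calibrate",
    "cpm_predict",
    "stability_select",
    "cross_sample_classify",
]


@dataclass
class CompositePredictors:
    """T_deg / T_eg composites and the signed metrics behind them."""

    t_deg: np.ndarray
    t_eg: np.ndarray
    member_metrics: list[tuple[str, int]]  # (metric name, sign)

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([self.t_deg, self.t_eg])


@dataclass
class PredictionOutcome:
    """Observed vs out-of-fold predicted outcome with permutation context."""

    observed: np.ndarray
    predicted: np.ndarray
    estimate: float
    kind: str  # "r" or "accuracy"
    per_group_accuracy: dict[str, float] | None = None
    null_distribution: np.ndarray | None = None
    ci95: tuple[float, float] | None = None
    p_perm: float | None = None
    significant: bool | None = None
    seed: int | None = None
    fold_assignments: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def metric_table(
    degree_auc: np.ndarray, efficiency_auc: np.ndarray, roi_labels: list[str]
) -> pd.DataFrame:
    """Subjects x metrics frame with columns ``deg:<roi>`` and ``eff:<roi>``."""
    cols = {f"deg:{l}": np.asarray(degree_auc)[:, j] for j, l in enumerate(roi_labels)}
    cols.update(
        {f"eff:{l}": np.asarray(efficiency_auc)[:, j] for j, l in enumerate(roi_labels)}
    )
    return pd.DataFrame(cols)


def unify_directions(
    metrics: pd.DataFrame, signs: dict[str, int]
) -> pd.DataFrame:
    """Multiply negatively associated metrics by -1; leave the rest alone."""
    out = metrics.copy()
    for name, s in signs.items():
        if s not in (-1, 1):
            raise ValueError(f"sign for {name!r} must be -1 or +1, got {s}")
        if name not in out.columns:
            raise ValueError(f"metric {name!r} not present")
        if s == -1:
            out[name] = -out[name]
    return out


def build_composites(
    metrics_unified: pd.DataFrame,
    degree_members: list[str],
    efficiency_members: list[str],
    signs: dict[str, int] | None = None,
) -> CompositePredictors:
    """Average the sign-unified member metrics into T_deg and T_eg."""
    if not degree_members and not efficiency_members:
        raise ValueError("at least one member metric is required")
    for m in list(degree_members) + list(efficiency_members):
        if m not in metrics_unified.columns:
            raise ValueError(f"metric {m!r} not present")
    n = len(metrics_unified)
    t_deg = (
        metrics_unified[degree_members].to_numpy().mean(axis=1)
        if degree_members
        else np.zeros(n)
    )
    t_eg = (
        metrics_unified[efficiency_members].to_numpy().mean(axis=1)
        if efficiency_members
        else np.zeros(n)
    )
    signs = signs or {}
    members = [
        (m, signs.get(m, 1)) for m in list(degree_members) + list(efficiency_members)
    ]
    return CompositePredictors(t_deg=t_deg, t_eg=t_eg, member_metrics=members)


def _ols_fit_predict(X_tr, y_tr, X_te):
    A = np.column_stack([np.ones(len(X_tr)), X_tr])
    beta = np.linalg.lstsq(A, y_tr, rcond=None)[0]
    return np.column_stack([np.ones(len(X_te)), X_te]) @ beta


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def kfold_predict_continuous(
    X: np.ndarray, y: np.ndarray, k: int = 10, seed: int = 0
) -> PredictionOutcome:
    """Out-of-fold OLS prediction; estimate = r(predicted, observed)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} subjects for {k}-fold CV")
    if np.any(~np.isfinite(y)):
        raise ValueError("outcome contains missing values")
    pred = np.empty(n)
    folds = np.empty(n, dtype=int)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (tr, te) in enumerate(kf.split(X)):
        if len(tr) < X.shape[1] + 2:
            raise ValueError(f"fold {f} has too few training rows")
        pred[te] = _ols_fit_predict(X[tr], y[tr], X[te])
        folds[te] = f
    return PredictionOutcome(
        observed=y,
        predicted=pred,
        estimate=_pearson(pred, y),
        kind="r",
        seed=seed,
        fold_assignments=folds,
    )


def kfold_classify(
    X: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    cutoff: float = 0.5,
) -> PredictionOutcome:
    """Out-of-fold logistic-regression classification at a probability cutoff.

    Folds are stratified by class so every training fold contains both
    groups.  Reported per-group accuracies map label 0 to "western" and
    label 1 to "eastern".
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if X.shape[0] != len(labels):
        X = X.T
    n = len(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("classification requires exactly two classes")
    prob = np.empty(n)
    folds = np.empty(n, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (tr, te) in enumerate(skf.split(X, labels)):
        # unpenalized maximum-likelihood logistic regression
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
        clf.fit(X[tr], labels[tr])
        prob[te] = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
        folds[te] = f
    pred = (prob > cutoff).astype(int)
    acc = float(np.mean(pred == labels))
    per_group = {
        "western": float(np.mean(pred[labels == 0] == 0)),
        "eastern": float(np.mean(pred[labels == 1] == 1)),
    }
    return PredictionOutcome(
        observed=labels.astype(int),
        predicted=pred,
        estimate=acc,
        kind="accuracy",
        per_group_accuracy=per_group,
        seed=seed,
        fold_assignments=folds,
        extra={"probability": prob},
    )


def permutation_calibrate(
    procedure,
    outcome: np.ndarray,
    observed_estimate: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation null for a CV estimate.

    ``procedure(outcome_permuted, rep_seed)`` must rerun the full
    cross-validation and return its estimate.  The 95% interval is the
    pair of values at the sorted 25th and 975th positions (1-based,
    scaled to ``n_perm``); significance means the observed estimate
    exceeds the upper bound.  A permutation p-value
    (1 + #{null >= observed}) / (n_perm + 1) is reported alongside.
    """
    if n_perm < 40:
        raise ValueError("n_perm < 40: percentile positions undefined")
    rng = np.random.default_rng(seed)
    outcome = np.asarray(outcome)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(outcome))
        null[i] = procedure(outcome[perm], int(rng.integers(2**31)))
    ordered = np.sort(null)
    # 1-based positions 25 and 975 at n_perm=1000; round half up in general
    lo = ordered[int(np.floor(0.025 * n_perm + 0.5)) - 1]
    hi = ordered[int(np.floor(0.975 * n_perm + 0.5)) - 1]
    p_perm = (1 + int(np.sum(null >= observed_estimate))) / (n_perm + 1)
    return {
        "null_distribution": null,
        "ci95": (float(lo), float(hi)),
        "significant": bool(observed_estimate > hi),
        "p_perm": float(p_perm),
    }


def calibrated_predict_continuous(
    X: np.ndarray, y: np.ndarray, k: int = 10, n_perm: int = 1000, seed: int = 0
) -> PredictionOutcome:
    """kfold_predict_continuous plus its permutation calibration."""
    out = kfold_predict_continuous(X, y, k=k, seed=seed)
    cal = permutation_calibrate(
        lambda y_perm, s: kfold_predict_continuous(X, y_perm, k=k, seed=s).estimate,
        y,
        out.estimate,
        n_perm=n_perm,
        seed=seed,
    )
    out.null_distribution = cal["null_distribution"]
    out.ci95 = cal["ci95"]
    out.significant = cal["significant"]
    out.p_perm = cal["p_perm"]
    return out


def calibrated_classify(
    X: np.ndarray, labels: np.ndarray, k: int = 10, n_perm: int = 1000, seed: int = 0
) -> PredictionOutcome:
    """kfold_classify plus its permutation calibration."""
    out = kfold_classify(X, labels, k=k, seed=seed)
    cal = permutation_calibrate(
        lambda l_perm, s: kfold_classify(X, l_perm, k=k, seed=s).estimate,
        labels,
        out.estimate,
        n_perm=n_perm,
        seed=seed,
    )
    out.null_distribution = cal["null_distribution"]
    out.ci95 = cal["ci95"]
    out.significant = cal["significant"]
    out.p_perm = cal["p_perm"]
    return out


def _train_screen(M: np.ndarray, y: np.ndarray, alpha: float):
    """Zero-order Pearson screen of every metric column against y."""
    n = len(y)
    Mc = M - M.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Mc**2).sum(axis=0) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Mc.T @ yc / denom, 0.0)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    from scipy import stats

    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return r, p < alpha


def cpm_predict(
    metrics: pd.DataFrame,
    y: np.ndarray,
    k: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[PredictionOutcome, list[set[str]]]:
    """Connectome-based predictive modeling on all nodal metrics.

    Within each training fold, metrics with a significant (p < alpha)
    zero-order correlation with the score are selected, sign-unified on
    the training data, averaged into fold-specific T_deg / T_eg, and an
    OLS model predicts the held-out fold.  Folds with no selected metric
    in either family predict the training mean (with a warning logged in
    the outcome).  Returns the outcome and the per-fold selected sets.
    """
    y = np.asarray(y, dtype=float)
    M = metrics.to_numpy(dtype=float)
    names = np.array(metrics.columns)
    is_deg = np.char.startswith(names.astype(str), "deg:")
    n = len(y)
    pred = np.empty(n)
    folds = np.empty(n, dtype=int)
    fold_sets: list[set[str]] = []
    warnings_log: list[str] = []
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (tr, te) in enumerate(kf.split(M)):
        r, keep = _train_screen(M[tr], y[tr], alpha)
        fold_sets.append(set(names[keep]))
        sel_deg = keep & is_deg
        sel_eff = keep & ~is_deg
        cols = []
        for sel in (sel_deg, sel_eff):
            if sel.any():
                signed = M[:, sel] * np.sign(r[sel])
                cols.append(signed.mean(axis=1))
        if not cols:
            warnings_log.append(f"fold {f}: no metric selected; predicting train mean")
            pred[te] = y[tr].mean()
        else:
            Xf = np.column_stack(cols)
            pred[te] = _ols_fit_predict(Xf[tr], y[tr], Xf[te])
        folds[te] = f
    out = PredictionOutcome(
        observed=y,
        predicted=pred,
        estimate=_pearson(pred, y),
        kind="r",
        seed=seed,
        fold_assignments=folds,
        extra={"warnings": warnings_log},
    )
    return out, fold_sets


def calibrated_cpm(
    metrics: pd.DataFrame,
    y: np.ndarray,
    k: int = 10,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[PredictionOutcome, list[set[str]]]:
    """cpm_predict plus its permutation calibration."""
    out, fold_sets = cpm_predict(metrics, y, k=k, alpha=alpha, seed=seed)
    cal = permutation_calibrate(
        lambda y_perm, s: cpm_predict(metrics, y_perm, k=k, alpha=alpha, seed=s)[
            0
        ].estimate,
        y,
        out.estimate,
        n_perm=n_perm,
        seed=seed,
    )
    out.null_distribution = cal["null_distribution"]
    out.ci95 = cal["ci95"]
    out.significant = cal["significant"]
    out.p_perm = cal["p_perm"]
    return out, fold_sets


def stability_select(fold_sets: list[set[str]], min_count: int = 10) -> set[str]:
    """Metrics selected in at least ``min_count`` of the folds."""
    from collections import Counter

    counts = Counter(m for s in fold_sets for m in s)
    return {m for m, c in counts.items() if c >= min_count}


def cross_sample_classify(
    selected: list[tuple[str, int]],
    metrics_both_groups: pd.DataFrame,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    n_perm: int | None = None,
) -> PredictionOutcome:
    """Classify group membership from composites of AHS-selected metrics.

    ``selected`` carries (metric name, sign) learned on the AHS cohort;
    composites are rebuilt on the combined two-group metric table and
    passed to the logistic-regression CV.
    """
    signs = {m: s for m, s in selected}
    deg_members = [m for m, _ in selected if m.startswith("deg:")]
    eff_members = [m for m, _ in selected if m.startswith("eff:")]
    unified = unify_directions(metrics_both_groups, signs)
    comp = build_composites(unified, deg_members, eff_members, signs)
    cols = [c for c, members in ((comp.t_deg, deg_members), (comp.t_eg, eff_members)) if members]
    X = np.column_stack(cols)
    if n_perm:
        out = calibrated_classify(X, labels, k=k, n_perm=n_perm, seed=seed)
    else:
        out = kfold_classify(X, labels, k=k, seed=seed)
    out.extra["member_metrics"] = comp.member_metrics
    return out
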