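"""Configuration, file formats, and the end-to-end pipeline runner.

All tabular artifacts are plain TSV/CSV with headers, matrices are dense
TSV, and reports/manifests are JSON, so every stage output can be
consumed without this package.  A run manifest records the configuration
hash, seeds, package version and accumulated warnings; two runs with the
same config and seed produce byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .graph_metrics import subject_metrics
from .group_inference import screen_nodes
from .network_construction import (
    BinaryGraphStack,
    CorrelationMatrix,
    RoiTimeSeries,
    absolute_values,
    compute_correlation,
    threshold_sweep,
    zero_negatives,
)
from .phenotype_association import metric_ahs_screen, node_fc_ahs_screen
from .predictive_modeling import (
    PredictionOutcome,
    build_composites,
    calibrated_classify,
    calibrated_cpm,
    calibrated_predict_continuous,
    cpm_predict,
    cross_sample_classify,
    metric_table,
    stability_select,
    unify_directions,
)

__all__ = [
    "RunConfig",
    "read_timeseries_dir",
    "read_phenotypes",
    "compute_cohort_metrics",
    "run_full_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of a pipeline run; collects the analysis constants
    (sparsity range 0.10-0.30, 10 folds, 1000 permutations, FDR q=0.05)."""

    timeseries_dir: str = ""
    phenotypes_path: str = ""
    out_dir: str = "netpheno_out"
    sparsity_min: float = 0.10
    sparsity_max: float = 0.30
    sparsity_step: float = 0.01
    negative_handling: str = "zero"  # or "absolute"
    use_fisher_z: bool = False
    fdr_q: float = 0.05
    screen_covariates: tuple[str, ...] = ("age", "sex", "motion", "site")
    association_covariates: tuple[str, ...] = ("sex", "age", "motion")
    k_folds: int = 10
    n_perm: int = 1000
    cpm_alpha: float = 0.05
    leakage_free: bool = False
    truncate_common: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sparsity_min < self.sparsity_max < 1:
            raise ValueError("require 0 < sparsity_min < sparsity_max < 1")
        if self.negative_handling not in ("zero", "absolute"):
            raise ValueError("negative_handling must be 'zero' or 'absolute'")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        self.screen_covariates = tuple(self.screen_covariates)
        self.association_covariates = tuple(self.association_covariates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["screen_covariates"] = list(self.screen_covariates)
        d["association_covariates"] = list(self.association_covariates)
        return d

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (paths excluded)."""
        d = self.to_dict()
        for key in ("timeseries_dir", "phenotypes_path", "out_dir"):
            d.pop(key)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------- readers

def read_timeseries_dir(path: str | Path) -> list[RoiTimeSeries]:
    """Load every subject TSV in a directory with consistent ROI ordering.

    The first file (sorted by name) fixes the reference label order;
    other files may list the same ROIs in any column order and are
    reordered to match.  Missing values and header mismatches raise.
    """
    files = sorted(Path(path).glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no .tsv time-series files in {path}")
    out: list[RoiTimeSeries] = []
    ref: list[str] | None = None
    offenders = []
    for f in files:
        df = pd.read_csv(f, sep="\t")
        if df.isna().any().any():
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise ValueError(
                f"missing value in {f.name} at row {r}, column {df.columns[c]!r}"
            )
        labels = list(df.columns)
        if ref is None:
            ref = labels
        elif set(labels) != set(ref):
            offenders.append(f.name)
            continue
        out.append(
            RoiTimeSeries(
                subject_id=f.stem, data=df[ref].to_numpy(dtype=float), roi_labels=list(ref)
            )
        )
    if offenders:
        raise ValueError(f"ROI header mismatch against {files[0].name}: {offenders}")
    return out


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Load and validate the phenotype CSV (subject_id, group, covariates, ahs)."""
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age", "sex", "motion", "site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dups}")
    if not set(df["group"].unique()) <= {0, 1}:
        raise ValueError("group column must be coded 0/1")
    if "ahs" not in df.columns:
        df["ahs"] = np.nan
    n_missing_ahs = int(df["ahs"].isna().sum())
    if n_missing_ahs:
        logger.info("phenotypes: %d subjects without AHS score", n_missing_ahs)
    return df


# ------------------------------------------------------------- middle layer

def _preprocess_correlation(ts: RoiTimeSeries, config: RunConfig) -> CorrelationMatrix:
    corr = compute_correlation(ts)
    if config.negative_handling == "absolute":
        return absolute_values(corr)
    return zero_negatives(corr)


def subject_stack(ts: RoiTimeSeries, config: RunConfig) -> BinaryGraphStack:
    corr = _preprocess_correlation(ts, config)
    return threshold_sweep(
        corr, config.sparsity_min, config.sparsity_max, config.sparsity_step
    )


def compute_cohort_metrics(
    timeseries: list[RoiTimeSeries], config: RunConfig | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Degree/efficiency AUC matrices (subjects x nodes) for a cohort."""
    config = config or RunConfig()
    labels = timeseries[0].roi_labels
    deg = np.empty((len(timeseries), len(labels)))
    eff = np.empty_like(deg)
    for i, ts in enumerate(timeseries):
        m = subject_metrics(subject_stack(ts, config), subject_id=ts.subject_id)
        deg[i] = m.degree_auc
        eff[i] = m.efficiency_auc
    return deg, eff, list(labels)


def write_correlation_tsv(corr: CorrelationMatrix, path: str | Path) -> None:
    pd.DataFrame(corr.values, index=corr.roi_labels, columns=corr.roi_labels).to_csv(
        path, sep="\t"
    )


def write_stack_edgelist(stack: BinaryGraphStack, path: str | Path) -> None:
    rows = []
    for k, S in enumerate(stack.sparsity_grid):
        iu, ju = np.nonzero(np.triu(stack.slice_at(k), k=1))
        for i, j in zip(iu, ju):
            rows.append((stack.roi_labels[i], stack.roi_labels[j], float(S)))
    pd.DataFrame(rows, columns=["node_i", "node_j", "S"]).to_csv(
        path, sep="\t", index=False
    )


def _outcome_dict(out: PredictionOutcome) -> dict:
    d = {
        "estimate": out.estimate,
        "kind": out.kind,
        "ci95": list(out.ci95) if out.ci95 else None,
        "p_perm": out.p_perm,
        "significant": out.significant,
        "per_group_accuracy": out.per_group_accuracy,
        "seed": out.seed,
        "member_metrics": out.extra.get("member_metrics"),
        "warnings": out.extra.get("warnings", []),
    }
    return d


# ------------------------------------------------------------ orchestration

def run_full_pipeline(config: RunConfig) -> dict:
    """construct -> metrics -> screen -> associate -> predict/classify.

    Returns the report bundle as a dict and writes every stage output
    under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    logger.info("stage construct: reading inputs")
    timeseries = read_timeseries_dir(config.timeseries_dir)
    phen = read_phenotypes(config.phenotypes_path)
    ids = [ts.subject_id for ts in timeseries]
    phen = phen.set_index("subject_id").loc[ids].reset_index()
    if config.truncate_common:
        t_min = min(ts.n_timepoints for ts in timeseries)
        timeseries = [
            RoiTimeSeries(ts.subject_id, ts.data[:t_min], ts.roi_labels)
            for ts in timeseries
        ]
        logger.info("truncated all subjects to %d common timepoints", t_min)
    logger.info("stage construct: %d subjects, %d ROIs", len(ids), timeseries[0].n_rois)

    logger.info("stage metrics: sparsity sweep and AUC")
    deg, eff, labels = compute_cohort_metrics(timeseries, config)
    metrics_long = pd.DataFrame(
        {
            "subject_id": np.repeat(ids, len(labels)),
            "roi": np.tile(labels, len(ids)),
            "degree_auc": deg.ravel(),
            "efficiency_auc": eff.ravel(),
        }
    )
    metrics_long.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)

    logger.info("stage screen: node-wise MANCOVA/ANCOVA with FDR")
    screen = screen_nodes(
        deg, eff, phen, labels,
        covariates=config.screen_covariates, q_level=config.fdr_q,
    )
    screen.table.to_csv(out_dir / "node_stats.tsv", sep="\t", index=False)
    (out_dir / "consistent_nodes.json").write_text(
        json.dumps(screen.consistent_nodes, indent=2)
    )
    logger.info("stage screen: %d consistent nodes", len(screen.consistent_nodes))

    report: dict = {
        "n_subjects": len(ids),
        "n_rois": len(labels),
        "consistent_nodes": screen.consistent_nodes,
    }

    has_ahs = phen["ahs"].notna()
    if screen.consistent_nodes and int(has_ahs.sum()) >= 3 * config.k_folds:
        logger.info("stage associate: metric-AHS partial correlations")
        assoc = metric_ahs_screen(
            deg, eff, labels, phen,
            nodes=screen.consistent_nodes,
            covariates=config.association_covariates,
            q_level=config.fdr_q,
        )
        assoc.table.to_csv(out_dir / "associations.tsv", sep="\t", index=False)
        report["selected_metrics"] = [list(s) for s in assoc.selected]

        fc_dir = out_dir / "fc_associations"
        fc_dir.mkdir(exist_ok=True)
        for roi in sorted({roi for roi, _m, _s in assoc.selected}):
            fc = node_fc_ahs_screen(
                roi, timeseries, phen,
                covariates=config.association_covariates,
                q_level=config.fdr_q,
                use_fisher_z=config.use_fisher_z,
            )
            fc.table.to_csv(fc_dir / f"{roi}.tsv", sep="\t", index=False)

        report.update(
            _prediction_stages(
                deg, eff, labels, phen, assoc.selected,
                screen.consistent_nodes, config, out_dir, warnings_log,
            )
        )
    else:
        msg = (
            "prediction stages skipped: no consistent nodes"
            if not screen.consistent_nodes
            else "prediction stages skipped: too few AHS subjects"
        )
        warnings_log.append(msg)
        logger.warning(msg)

    manifest = {
        "package_version": _version,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_subjects": len(ids),
        "warnings": warnings_log,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out_dir / "prediction_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str)
    )
    return report


def _prediction_stages(
    deg, eff, labels, phen, selected, consistent_nodes, config, out_dir, warnings_log
) -> dict:
    """Intrasample prediction, cross-sample classification, CPM variant."""
    report: dict = {}
    metrics_all = metric_table(deg, eff, labels)
    has_ahs = phen["ahs"].notna().to_numpy()
    y = phen.loc[has_ahs, "ahs"].to_numpy(dtype=float)
    labels01 = phen["group"].to_numpy(dtype=int)

    signs = {f"{'deg' if m == 'degree_auc' else 'eff'}:{roi}": s for roi, m, s in selected}
    deg_members = [k for k in signs if k.startswith("deg:")]
    eff_members = [k for k in signs if k.startswith("eff:")]

    if not signs:
        warnings_log.append("no AHS-associated metrics; prediction stages skipped")
        return report

    logger.info("stage predict: intrasample %d-fold CV", config.k_folds)
    if config.leakage_free:
        # re-estimate membership and signs inside every training fold,
        # screening all metrics of the consistent nodes
        consistent_cols = [
            c for roi in consistent_nodes for c in (f"deg:{roi}", f"eff:{roi}")
        ]
        sub = metrics_all.loc[has_ahs, consistent_cols]
        intra, _sets = cpm_predict(
            sub, y, k=config.k_folds, alpha=config.cpm_alpha, seed=config.seed
        )
        from .predictive_modeling import permutation_calibrate

        cal = permutation_calibrate(
            lambda y_perm, s: cpm_predict(
                sub, y_perm, k=config.k_folds, alpha=config.cpm_alpha, seed=s
            )[0].estimate,
            y,
            intra.estimate,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        intra.ci95, intra.p_perm = cal["ci95"], cal["p_perm"]
        intra.significant = cal["significant"]
        intra.null_distribution = cal["null_distribution"]
    else:
        unified = unify_directions(metrics_all, signs)
        comp = build_composites(unified, deg_members, eff_members, signs)
        X_ahs = comp.X[has_ahs]
        intra = calibrated_predict_continuous(
            X_ahs, y, k=config.k_folds, n_perm=config.n_perm, seed=config.seed
        )
        intra.extra["member_metrics"] = comp.member_metrics
    report["intrasample"] = _outcome_dict(intra)

    logger.info("stage classify: cross-sample logistic CV")
    cross = cross_sample_classify(
        list(signs.items()), metrics_all, labels01,
        k=config.k_folds, seed=config.seed, n_perm=config.n_perm,
    )
    report["cross_sample"] = _outcome_dict(cross)

    logger.info("stage cpm: within-fold screening on all metrics")
    cpm_out, fold_sets = calibrated_cpm(
        metrics_all.loc[has_ahs].reset_index(drop=True), y,
        k=config.k_folds, alpha=config.cpm_alpha,
        n_perm=config.n_perm, seed=config.seed,
    )
    report["cpm_intrasample"] = _outcome_dict(cpm_out)
    stable = stability_select(fold_sets, min_count=config.k_folds)
    report["cpm_stable_metrics"] = sorted(stable)
    if stable:
        # signs for the stable set from the AHS cohort
        M = metrics_all.loc[has_ahs]
        stable_signs = [
            (m, 1 if np.corrcoef(M[m], y)[0, 1] >= 0 else -1) for m in sorted(stable)
        ]
        cpm_cross = cross_sample_classify(
            stable_signs, metrics_all, labels01,
            k=config.k_folds, seed=config.seed, n_perm=config.n_perm,
        )
        report["cpm_cross_sample"] = _outcome_dict(cpm_cross)
    else:
        warnings_log.append("CPM: no metric stable across all folds; cross-sample skipped")

    # per-subject predictions and null distributions
    pred_rows = pd.DataFrame(
        {
            "subject_id": phen.loc[has_ahs, "subject_id"].to_numpy(),
            "observed_ahs": intra.observed,
            "predicted_ahs": intra.predicted,
            "fold": intra.fold_assignments,
        }
    )
    pred_rows.to_csv(out_dir / "predictions.tsv", sep="\t", index=False)
    nulls = {}
    for name, outc in (
        ("intrasample_r", intra),
        ("cross_sample_accuracy", cross),
        ("cpm_r", cpm_out),
    ):
        if outc.null_distribution is not None:
            nulls[name] = outc.null_distribution
    if nulls:
        pd.DataFrame(nulls).to_csv(out_dir / "null_distribution.tsv", sep="\t", index=False)
    return report
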