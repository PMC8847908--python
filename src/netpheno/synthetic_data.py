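"""Synthetic multi-subject cohorts with known ground truth.

Emulates a two-group resting-state study: each group has a population
connectome (a symmetric nonnegative weight matrix); group 1 carries a
planted effect on the edges incident to designated nodes; each subject
gets an individual network by jittering per-node connection strengths;
ROI time series are drawn from the zero-mean multivariate Gaussian whose
covariance is the subject's implied covariance.  A holistic-thinking
("AHS-like") score is linearly coupled to the subject's *noiseless* nodal
network metrics — computed by running the real thresholding/metric
pipeline on the subject's population correlation matrix — so planted
phenotype effects must propagate through the same code path that
analyzes the sampled data.  Covariates (age, sex, motion, site) are drawn
with configurable group confounds.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_metrics import subject_metrics
from .network_construction import (
    CorrelationMatrix,
    RoiTimeSeries,
    threshold_sweep,
    zero_negatives,
)

__all__ = [
    "GroundTruthNetwork",
    "CohortSpec",
    "CohortDataset",
    "make_ground_truth",
    "sample_subject_timeseries",
    "generate_cohort",
    "write_cohort",
]

#: ridge margin added beyond the minimal value that makes the implied
#: covariance positive definite
PD_MARGIN = 0.01

#: metric names a phenotype coupling may reference
METRIC_NAMES = ("degree_auc", "efficiency_auc")


def _pd_ridge(weights: np.ndarray) -> float:
    """Smallest ridge making ``weights + ridge*I`` positive definite, plus margin."""
    min_eig = float(np.linalg.eigvalsh(weights)[0])
    return max(0.0, -min_eig) + PD_MARGIN


@dataclass
class GroundTruthNetwork:
    """Population connectome behind the simulated group difference.

    ``base_weights`` is the group-0 connectome.  In group 1 every edge
    incident to an ``effect_node`` is scaled by ``1 + effect_delta``, so
    the group difference enters at the edge level and reaches the nodal
    metrics only through the analysis pipeline itself.
    """

    n_nodes: int
    base_weights: np.ndarray
    effect_nodes: frozenset[int]
    effect_delta: float

    def __post_init__(self) -> None:
        W = np.asarray(self.base_weights, dtype=float)
        if W.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("base_weights shape does not match n_nodes")
        if not np.allclose(W, W.T):
            raise ValueError("base_weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("base_weights must have a zero diagonal")
        if np.any(W < 0):
            raise ValueError("base_weights must be nonnegative")
        bad = [i for i in self.effect_nodes if not 0 <= i < self.n_nodes]
        if bad:
            raise ValueError(f"effect nodes out of range: {bad}")
        self.base_weights = W
        self.effect_nodes = frozenset(int(i) for i in self.effect_nodes)

    @property
    def roi_labels(self) -> list[str]:
        return [f"roi{i:03d}" for i in range(self.n_nodes)]

    def group_weights(
        self, group: int, node_gains: np.ndarray | None = None
    ) -> np.ndarray:
        """Weight matrix for one subject: group effect plus per-node gains."""
        if group not in (0, 1):
            raise ValueError("group must be 0 or 1")
        W = self.base_weights.copy()
        if group == 1 and self.effect_nodes and self.effect_delta != 0.0:
            idx = sorted(self.effect_nodes)
            W[idx, :] *= 1.0 + self.effect_delta
            W[:, idx] *= 1.0 + self.effect_delta
            # edges between two effect nodes were scaled twice; undo one factor
            sub = np.ix_(idx, idx)
            W[sub] /= 1.0 + self.effect_delta
        if node_gains is not None:
            g = np.asarray(node_gains, dtype=float)
            if g.shape != (self.n_nodes,):
                raise ValueError("node_gains must have one entry per node")
            W = W * np.outer(g, g)
            np.fill_diagonal(W, 0.0)
        return W

    def implied_covariance(
        self, group: int, noise_sd: float = 0.0, node_gains: np.ndarray | None = None
    ) -> np.ndarray:
        """Covariance = weights + (ridge + noise_sd^2) * I.

        The ridge is the smallest value making the matrix positive
        definite plus a 0.01 margin; ``noise_sd`` adds observation noise
        on the diagonal, shrinking all implied correlations.
        """
        W = self.group_weights(group, node_gains)
        lam = _pd_ridge(W)
        cov = W + (lam + noise_sd**2) * np.eye(self.n_nodes)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - margin should prevent
            raise np.linalg.LinAlgError(
                f"implied covariance not positive definite after shrinkage "
                f"(min eig {np.linalg.eigvalsh(cov)[0]:.3e})"
            ) from exc
        return cov

    def implied_correlation(
        self, group: int, noise_sd: float = 0.0, node_gains: np.ndarray | None = None
    ) -> np.ndarray:
        cov = self.implied_covariance(group, noise_sd, node_gains)
        sd = np.sqrt(np.diag(cov))
        return cov / np.outer(sd, sd)


def make_ground_truth(
    n_nodes: int,
    density: float,
    effect_nodes: set[int] | frozenset[int] = frozenset(),
    effect_delta: float = 0.0,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.2, 0.6),
) -> GroundTruthNetwork:
    """Random population connectome with ~``density`` fraction of edges present.

    Each off-diagonal pair is an edge independently with probability
    ``density``; present edges get weights uniform in ``weight_range``.
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_nodes, k=1)
    present = rng.random(iu.size) < density
    w = np.where(present, rng.uniform(*weight_range, size=iu.size), 0.0)
    W = np.zeros((n_nodes, n_nodes))
    W[iu, ju] = w
    W += W.T
    return GroundTruthNetwork(
        n_nodes=n_nodes,
        base_weights=W,
        effect_nodes=frozenset(effect_nodes),
        effect_delta=effect_delta,
    )


def sample_subject_timeseries(
    network: GroundTruthNetwork,
    group: int,
    n_timepoints: int,
    noise_sd: float,
    seed: int,
    subject_id: str = "sub",
    node_gains: np.ndarray | None = None,
    ar1: float = 0.0,
) -> RoiTimeSeries:
    """Draw a T x R series from the subject's implied Gaussian.

    With ``ar1 > 0`` consecutive timepoints follow an AR(1) process whose
    stationary covariance still equals the implied covariance.
    """
    cov = network.implied_covariance(group, noise_sd, node_gains)
    L = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_timepoints, network.n_nodes)) @ L.T
    if ar1 != 0.0:
        if not -1.0 < ar1 < 1.0:
            raise ValueError("ar1 coefficient must lie in (-1, 1)")
        x = np.empty_like(z)
        x[0] = z[0]
        c = np.sqrt(1.0 - ar1**2)
        for t in range(1, n_timepoints):
            x[t] = ar1 * x[t - 1] + c * z[t]
        z = x
    return RoiTimeSeries(
        subject_id=subject_id, data=z, roi_labels=network.roi_labels
    )


@dataclass
class CohortSpec:
    """Generating parameters for a two-group cohort.

    ``phenotype_weights`` maps ``(node_index, metric_name)`` to a linear
    coupling coefficient; the AHS-like score is the weighted sum of the
    subject's noiseless nodal metrics plus Gaussian noise.  If
    ``phenotype_target_r`` is set, ``phenotype_noise_sd`` is replaced by
    the value that makes the population correlation between the noiseless
    weighted signal and the score equal that target.
    """

    n_per_group: int = 60
    n_timepoints: int = 150
    noise_sd: float = 0.5
    phenotype_weights: dict[tuple[int, str], float] = field(default_factory=dict)
    phenotype_noise_sd: float = 1.0
    covariate_confounding: dict[str, float] = field(
        default_factory=lambda: {"age": -9.0, "sex": -0.2, "motion": 0.1}
    )
    seed: int = 0
    subject_gain_sd: float = 0.15
    ar1: float = 0.0
    phenotype_target_r: float | None = None
    sparsity: tuple[float, float, float] = (0.10, 0.30, 0.01)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.noise_sd <= 0 or self.phenotype_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        if self.subject_gain_sd < 0:
            raise ValueError("subject_gain_sd must be nonnegative")
        if self.phenotype_target_r is not None and not 0 < self.phenotype_target_r < 1:
            raise ValueError("phenotype_target_r must lie in (0, 1)")
        for (node, metric) in self.phenotype_weights:
            if metric not in METRIC_NAMES:
                raise ValueError(f"unknown metric {metric!r} in phenotype_weights")


@dataclass
class CohortDataset:
    """Generated cohort: time series, phenotypes, and the generating truth."""

    timeseries: list[RoiTimeSeries]
    phenotypes: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        ids = [ts.subject_id for ts in self.timeseries]
        if len(set(ids)) != len(ids):
            raise ValueError("subject IDs must be unique")
        if set(self.phenotypes["subject_id"]) != set(ids):
            raise ValueError("phenotype rows must match time-series subjects 1:1")


def _true_nodal_metrics(
    network: GroundTruthNetwork,
    group: int,
    noise_sd: float,
    node_gains: np.ndarray,
    sparsity: tuple[float, float, float],
):
    """Noiseless metrics: run the real pipeline on the implied correlation."""
    corr = CorrelationMatrix(
        values=network.implied_correlation(group, noise_sd, node_gains),
        roi_labels=network.roi_labels,
    )
    stack = threshold_sweep(zero_negatives(corr), *sparsity)
    return subject_metrics(stack)


def generate_cohort(spec: CohortSpec, network: GroundTruthNetwork) -> CohortDataset:
    """Simulate two groups of subjects under one ground-truth network."""
    if spec.n_timepoints <= network.n_nodes:
        warnings.warn(
            f"n_timepoints ({spec.n_timepoints}) <= n_nodes ({network.n_nodes}); "
            "correlation estimates will be rank deficient",
            stacklevel=2,
        )
    for (node, _metric) in spec.phenotype_weights:
        if not 0 <= node < network.n_nodes:
            raise ValueError(f"phenotype_weights references unknown node {node}")

    rng = np.random.default_rng(spec.seed)
    conf = {"age": 0.0, "sex": 0.0, "motion": 0.0, **spec.covariate_confounding}
    need_truth_metrics = any(w != 0 for w in spec.phenotype_weights.values())

    timeseries: list[RoiTimeSeries] = []
    rows = []
    signal = np.zeros(2 * spec.n_per_group)
    true_deg = []
    true_eff = []
    k = 0
    for group in (0, 1):
        for _ in range(spec.n_per_group):
            sid = f"sub-{k:04d}"
            gains = np.clip(
                1.0 + spec.subject_gain_sd * rng.standard_normal(network.n_nodes),
                0.05,
                None,
            )
            ts = sample_subject_timeseries(
                network,
                group,
                spec.n_timepoints,
                spec.noise_sd,
                seed=int(rng.integers(2**31)),
                subject_id=sid,
                node_gains=gains,
                ar1=spec.ar1,
            )
            timeseries.append(ts)
            if need_truth_metrics:
                tm = _true_nodal_metrics(
                    network, group, spec.noise_sd, gains, spec.sparsity
                )
                true_deg.append(tm.degree_auc)
                true_eff.append(tm.efficiency_auc)
                signal[k] = sum(
                    w * (tm.degree_auc[n] if m == "degree_auc" else tm.efficiency_auc[n])
                    for (n, m), w in spec.phenotype_weights.items()
                )
            age = 30.0 + 10.0 * rng.standard_normal() + group * conf["age"]
            sex = int(rng.random() < np.clip(0.5 + group * conf["sex"], 0.05, 0.95))
            motion = float(
                np.exp(np.log(0.10) + 0.5 * rng.standard_normal() + group * conf["motion"])
            )
            site_p = [0.5, 0.3, 0.2] if group == 0 else [0.2, 0.3, 0.5]
            site = int(rng.choice(3, p=site_p))
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "motion": motion,
                    "site": site,
                }
            )
            k += 1

    noise_sd = spec.phenotype_noise_sd
    if spec.phenotype_target_r is not None and need_truth_metrics:
        s_sd = float(np.std(signal))
        if s_sd == 0:
            raise ValueError("phenotype signal is constant; cannot target a correlation")
        r = spec.phenotype_target_r
        noise_sd = s_sd * np.sqrt(1.0 / r**2 - 1.0)
    ahs = signal + noise_sd * rng.standard_normal(signal.size)

    phen = pd.DataFrame(rows)
    phen["ahs"] = ahs
    truth = {
        "network": network,
        "spec": spec,
        "phenotype_noise_sd_used": float(noise_sd),
        "true_degree_auc": np.array(true_deg) if need_truth_metrics else None,
        "true_efficiency_auc": np.array(true_eff) if need_truth_metrics else None,
        "phenotype_signal": signal if need_truth_metrics else None,
    }
    return CohortDataset(timeseries=timeseries, phenotypes=phen, truth=truth)


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> None:
    """Write one TSV per subject, phenotypes.csv, and truth.json."""
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for ts in dataset.timeseries:
        df = pd.DataFrame(ts.data, columns=ts.roi_labels)
        df.to_csv(ts_dir / f"{ts.subject_id}.tsv", sep="\t", index=False)
    dataset.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    net: GroundTruthNetwork = dataset.truth["network"]
    spec: CohortSpec = dataset.truth["spec"]
    payload = {
        "n_nodes": net.n_nodes,
        "effect_nodes": sorted(net.effect_nodes),
        "effect_delta": net.effect_delta,
        "base_weights": net.base_weights.tolist(),
        "n_per_group": spec.n_per_group,
        "n_timepoints": spec.n_timepoints,
        "noise_sd": spec.noise_sd,
        "phenotype_weights": [
            [int(n), m, float(w)] for (n, m), w in spec.phenotype_weights.items()
        ],
        "phenotype_noise_sd_used": dataset.truth["phenotype_noise_sd_used"],
        "covariate_confounding": spec.covariate_confounding,
        "subject_gain_sd": spec.subject_gain_sd,
        "ar1": spec.ar1,
        "sparsity": list(spec.sparsity),
        "seed": spec.seed,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2))
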