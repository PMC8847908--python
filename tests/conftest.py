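import numpy as np
import pytest

import netpheno as nph


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_network():
    """12-node ground-truth connectome with 3 planted effect nodes."""
    return nph.make_ground_truth(
        n_nodes=12, density=0.35, effect_nodes={2, 5, 9}, effect_delta=1.0, seed=5
    )


@pytest.fixture(scope="session")
def small_cohort(small_network):
    """Small planted cohort exercised by several downstream tests.

    Weights are scaled so the degree and efficiency couplings contribute
    comparably to the phenotype signal (efficiency AUC varies on a ~10x
    smaller scale than degree AUC).
    """
    spec = nph.CohortSpec(
        n_per_group=60,
        n_timepoints=150,
        seed=18,
        phenotype_weights={(2, "degree_auc"): 1.0, (5, "efficiency_auc"): -10.0},
        phenotype_target_r=0.8,
    )
    return nph.generate_cohort(spec, small_network)


@pytest.fixture(scope="session")
def small_cohort_metrics(small_cohort):
    deg, eff, labels = nph.compute_cohort_metrics(small_cohort.timeseries)
    return deg, eff, labels
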