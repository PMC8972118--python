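import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emanet as en

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """7-node two-group generating network without a group difference."""
    return en.generate_true_network(n_groups=2, sparsity=0.3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    cfg = en.SimulationConfig(n_subjects_per_group=20, missing_rate=0.1, seed=5)
    return en.generate_dataset(small_spec, cfg)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    table = en.assemble_analysis_table(small_dataset)
    return en.nonparanormal_transform(table)


def make_dataset(
    n_subjects=20,
    n_nodes=3,
    seed=0,
    sparsity=0.3,
    group_delta=None,
    missing_rate=0.1,
    random_effect_sd=0.05,
    subject_mean_sd=1.0,
    innovation_sd=1.0,
    n_days=7,
    beeps_per_day=8,
):
    """Convenience wrapper used across tests: spec + dataset in one call."""
    labels = en.VARIABLES[:n_nodes] if n_nodes < 7 else en.VARIABLES
    spec = en.generate_true_network(
        n_groups=2,
        sparsity=sparsity,
        group_delta=group_delta,
        seed=seed,
        node_labels=labels,
        random_effect_sd=random_effect_sd,
        innovation_sd=innovation_sd,
    )
    cfg = en.SimulationConfig(
        n_subjects_per_group=n_subjects,
        missing_rate=missing_rate,
        subject_mean_sd=subject_mean_sd,
        n_days=n_days,
        beeps_per_day=beeps_per_day,
        seed=seed + 1,
    )
    return spec, en.generate_dataset(spec, cfg)
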