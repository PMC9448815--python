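import numpy as np
import pytest

from transdx_cpm import SimulationConfig, nested_cv, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """80 subjects, 20 ROIs, 10 planted edges, two runs; no group shifts."""
    config = SimulationConfig(
        n_subjects=80, n_roi=20, n_true_edges=10, seed=42,
    ).without_group_effects()
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_cv(small_cohort):
    dataset, _, _ = small_cohort
    return nested_cv(dataset, rounds=2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
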