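import numpy as np
import pytest

from stratcare import CohortConfig, PolicyConfig
from stratcare.allocation import allocate_cohort
from stratcare.cohort import generate_cohort, simulate_pathway_and_outcomes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_patients=400, n_clinicians=10, seed=7)


@pytest.fixture(scope="session")
def completed_cohort(small_config):
    """One fully simulated small trial (baseline + pathway + endpoints)."""
    cohort = generate_cohort(small_config, seed=7)
    decisions = allocate_cohort(cohort, PolicyConfig(), seed=7)
    return simulate_pathway_and_outcomes(
        cohort, decisions, small_config, PolicyConfig(), seed=7
    )


@pytest.fixture(scope="session")
def large_training_cohort():
    """A larger cohort for model-fitting tests (shared across the session)."""
    config = CohortConfig(n_patients=4000, seed=11)
    cohort = generate_cohort(config, seed=11)
    decisions = allocate_cohort(cohort, PolicyConfig(), seed=11)
    return simulate_pathway_and_outcomes(
        cohort, decisions, config, PolicyConfig(), seed=11
    )
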