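import numpy as np
import pytest

from rmfaces import CohortConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-per-group simulated cohort shared by I/O and pipeline tests."""
    config = CohortConfig(n_per_group=2, seed=7)
    trials, participants = simulate_cohort(config)
    return trials, participants
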