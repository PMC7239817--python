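import numpy as np
import pytest

from hfnet.cohortsim import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default 94-subject cohort, shared across tests (seed-fixed)."""
    table, truth = simulate_cohort(CohortConfig(seed=20240901))
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
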