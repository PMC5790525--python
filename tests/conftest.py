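import numpy as np
import pytest

from neoscout.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One small deterministic cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=7, n_genes=60, n_variants=20))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
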