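import numpy as np
import pytest

from pansvkit import simulate


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort that keeps every stage fast but non-trivial."""
    return simulate.SimulationConfig(seed=7, n_sv=200, n_genes=120)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate.simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
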