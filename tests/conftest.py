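import numpy as np
import pytest

from wpla.simulate import simulate_dataset
from wpla.solver import Hyperparams, solve_wpla


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def case1_sim():
    """One benchmark dataset under Gaussian noise, shared across tests."""
    return simulate_dataset(1, seed=1)


@pytest.fixture(scope="session")
def case1_fit(case1_sim):
    """Default-tuned fit of the shared dataset (expensive: run once)."""
    D = case1_sim.D.values
    return solve_wpla(D, Hyperparams.from_data(D))
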