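import numpy as np
import pytest

from richsync.params import sample_params
from richsync.simulate import run_simulation


@pytest.fixture(scope="session")
def small_params():
    """A small, fast parameterization used across tests."""
    return sample_params(7, overrides={"S": 18, "P": 9})


@pytest.fixture(scope="session")
def small_cube(small_params):
    return run_simulation(small_params, T_total=80, burn_in=40)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
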