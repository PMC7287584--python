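import numpy as np
import pytest

from gaitvar.synthetic import GaitSimParams, simulate_session


@pytest.fixture(scope="session")
def noiseless_params():
    return GaitSimParams(seed=11, duration_s=60.0, noise_force_N=0.0, noise_acc_g=0.0)


@pytest.fixture(scope="session")
def noiseless_session(noiseless_params):
    """One noise-free 60 s walk shared across detector tests."""
    return simulate_session(noiseless_params)


@pytest.fixture(scope="session")
def noisy_params():
    return GaitSimParams(seed=12, duration_s=60.0)


@pytest.fixture(scope="session")
def noisy_session(noisy_params):
    return simulate_session(noisy_params)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
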