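import numpy as np
import pytest

from segma import PhantomParams, generate_phantom, generate_population


@pytest.fixture(scope="session")
def tiny_params():
    """Small, quiet phantom for fast unit tests."""
    return PhantomParams(shape=(24, 24, 24), noise_sd=4.0, bias_amplitude=0.1,
                         warp_sd=0.4, seed=11)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_params):
    return generate_phantom(tiny_params)


@pytest.fixture(scope="session")
def tiny_population(tiny_params):
    return generate_population(4, tiny_params)


@pytest.fixture(scope="session")
def clean_params():
    """Noiseless, bias-free, warp-free phantom parameters."""
    return PhantomParams(shape=(20, 20, 20), noise_sd=0.0, bias_amplitude=0.0,
                         warp_sd=0.0, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
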