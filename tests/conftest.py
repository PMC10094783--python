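import numpy as np
import pytest

from scapulometry.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def canonical_phantom():
    """Noiseless phantom aligned with the canonical frame (0 deg / 0 deg / 50%)."""
    params = PhantomParams(
        true_version=0.0,
        true_inclination=0.0,
        true_subluxation=50.0,
        noise_sd=0.0,
        ridge_bow=0.0,
        seed=11,
    )
    return generate_phantom(params)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless straight-ridge phantom with study-typical deformity."""
    params = PhantomParams(
        true_version=-9.4,
        true_inclination=8.1,
        true_subluxation=60.1,
        noise_sd=0.0,
        ridge_bow=0.0,
        seed=23,
    )
    return generate_phantom(params)


@pytest.fixture(scope="session")
def bowed_phantom():
    """Noiseless phantom with a 6 mm ridge bow (the variant-splitting case)."""
    params = PhantomParams(noise_sd=0.0, ridge_bow=6.0, seed=29)
    return generate_phantom(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
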