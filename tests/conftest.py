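import numpy as np
import pytest

from myoseg.phantom import PhantomConfig, generate_slice


@pytest.fixture(scope="session")
def thigh_slice():
    return generate_slice(PhantomConfig(district="thigh", image_size=96, seed=7))


@pytest.fixture(scope="session")
def leg_slice():
    return generate_slice(PhantomConfig(district="leg", image_size=96, seed=11))


@pytest.fixture(scope="session")
def clean_thigh_slice():
    """Noise/bias-free thigh phantom: exact tissue intensities for geometry checks."""
    return generate_slice(
        PhantomConfig(district="thigh", image_size=96, seed=3, noise_sd=0.0,
                      bias_field_amplitude=0.0)
    )


@pytest.fixture(scope="session")
def clean_leg_slice():
    return generate_slice(
        PhantomConfig(district="leg", image_size=96, seed=5, noise_sd=0.0,
                      bias_field_amplitude=0.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
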