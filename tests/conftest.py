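import numpy as np
import pytest

from radialcs import (
    NoiseModel,
    PhantomSpec,
    add_noise,
    encode,
    make_phantom,
    make_radial_mask,
)


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(PhantomSpec(64))


@pytest.fixture(scope="session")
def phantom256():
    return make_phantom(PhantomSpec(256))


@pytest.fixture(scope="session")
def small_problem(phantom64):
    """64x64 Shepp-Logan, Gaussian sigma=20, pseudo-radial rate 0.3."""
    mask = make_radial_mask((64, 64), sensing_rate=0.3, seed=1)
    noisy = add_noise(phantom64, NoiseModel(family="gaussian", sigma=20, seed=1))
    obs = encode(noisy, mask)
    return phantom64, obs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
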