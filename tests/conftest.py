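import numpy as np
import pytest

from otomorph import IntensityVolume, BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    def make(shape=(8, 8, 8), seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return IntensityVolume(r.uniform(0.0, 1.0, shape))
    return make


@pytest.fixture
def constant_volume():
    def make(value=0.3, shape=(6, 6, 6)):
        return IntensityVolume(np.full(shape, value))
    return make


@pytest.fixture
def random_mask(rng):
    def make(shape=(16, 16, 16), p=0.3, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return BinaryMask(r.random(shape) < p)
    return make
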