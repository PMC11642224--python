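import numpy as np
import pytest

from oactool import OCTVolume
from oactool.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """A tiny random linear-intensity volume for I/O and estimator tests."""
    data = rng.random((16, 6, 5)) + 0.01
    return OCTVolume(data, dz=2.6, dx=11.7, dy=11.7)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, vessel-free, defect-free default phantom (shared, read-only)."""
    spec = PhantomSpec(shape=(512, 48, 48))
    return generate_phantom(spec)
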