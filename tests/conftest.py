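import numpy as np
import pytest

from hippoatlas.imaging import Volume3D
from hippoatlas.phantoms import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free, unjittered phantom with both hippocampi."""
    spec = PhantomSpec(noise_sd=0.0, bias_amplitude=0.0, max_translation=0.0, max_rotation_deg=0.0, seed=5)
    vol, left, right = make_phantom(spec)
    return spec, vol, left, right


@pytest.fixture(scope="session")
def small_phantom():
    """32-voxel grid phantom with small hippocampi, for fast registration tests."""
    spec = PhantomSpec(
        shape=(32, 32, 32),
        volume_left_mm3=400.0,
        volume_right_mm3=400.0,
        noise_sd=0.01,
        bias_amplitude=0.0,
        max_translation=0.0,
        max_rotation_deg=0.0,
        seed=9,
    )
    return (spec,) + make_phantom(spec)


@pytest.fixture
def random_volume(rng):
    return Volume3D(rng.random((8, 8, 8)).astype(np.float32))
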