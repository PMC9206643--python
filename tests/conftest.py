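import numpy as np
import pytest

from parstain.phantom import PhantomSpec, sample_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """128 px phantom with warp, noise and all structure classes."""
    spec = PhantomSpec(height_px=128, width_px=128, seed=3)
    return sample_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free 128 px phantom (deterministic channel forward model)."""
    spec = PhantomSpec(
        height_px=128, width_px=128, noise_sd=(0.0, 0.0, 0.0), seed=4
    )
    return sample_phantom(spec)


@pytest.fixture(scope="session")
def medium_phantom():
    """256 px phantom used for registration-recovery checks."""
    spec = PhantomSpec(height_px=256, width_px=256, warp_amplitude_px=5.0, seed=7)
    return sample_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
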