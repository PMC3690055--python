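import numpy as np
import pytest
from scipy.ndimage import gaussian_filter


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_texture(seed: int = 0, shape=(200, 400), smooth: float = 1.5) -> np.ndarray:
    """Contrasty smoothed-noise texture with trackable corners (uint8)."""
    r = np.random.default_rng(seed)
    tex = gaussian_filter(r.uniform(0.0, 1.0, shape), smooth)
    tex -= tex.min()
    tex /= tex.max()
    return (10 + 235 * tex).astype(np.uint8)


@pytest.fixture
def texture():
    return make_texture()


@pytest.fixture
def textured_frame(texture):
    return texture[40:160, 40:200]
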