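import numpy as np
import pytest

from calfmfi.phantom import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_spec():
    """Noise-free, bias-free, marbling-free phantom spec."""
    return PhantomSpec(fat_fraction=0.0, noise_sigma=0.0, bias_amplitude=0.0)


def disk_mask(radius_px: float, shape=(128, 128), center=None) -> np.ndarray:
    """Analytic disk rasterized by pixel-centre inclusion."""
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius_px


def annulus_mask(r_inner_px: float, r_outer_px: float, shape=(256, 256),
                 center=None) -> np.ndarray:
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    return (d <= r_outer_px) & (d > r_inner_px)
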