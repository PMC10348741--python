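import numpy as np
import pytest

PIXEL_UM = 0.105


@pytest.fixture(scope="session")
def solid_ellipse():
    """Noise-free two-intensity image of a solid ellipse, semi-axes
    a = 10 µm, b = 4.5 µm, at 105 nm pixels."""
    yy, xx = np.mgrid[0:256, 0:256]
    a, b = 10.0 / PIXEL_UM, 4.5 / PIXEL_UM
    mask = ((xx - 128) / a) ** 2 + ((yy - 128) / b) ** 2 <= 1
    return np.where(mask, 200.0, 10.0), mask, PIXEL_UM


@pytest.fixture(scope="session")
def textured_frame():
    """Smooth random texture for registration tests."""
    from scipy import ndimage

    rng = np.random.default_rng(0)
    return ndimage.gaussian_filter(rng.random((128, 128)), 2)
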