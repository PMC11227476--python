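import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def textured_nucleus_image(shape=(128, 128), seed=0, noise=2.0):
    """2D nucleus-like test image: soft ellipse with granular interior."""
    r = np.random.default_rng(seed)
    Y, X = shape
    yy, xx = np.mgrid[0:Y, 0:X]
    blob = ((yy - Y / 2) / (0.32 * Y)) ** 2 + ((xx - X / 2) / (0.4 * X)) ** 2 <= 1
    tex = ndimage.gaussian_filter(r.normal(0, 1, shape), 2.0)
    tex /= tex.std()
    img = np.where(blob, 80.0 * (1 + 0.4 * tex), 0.0)
    img = ndimage.gaussian_filter(img, 1.0) + 20.0
    if noise:
        img = img + r.normal(0, noise, shape)
    return img, blob


@pytest.fixture
def nucleus_image():
    return textured_nucleus_image()
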