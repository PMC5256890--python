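import numpy as np
import pytest

from spinetrack.synthetic import Microscope, default_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_image(rng):
    """Smooth but feature-rich image: blurred noise + a bright blob."""
    from scipy import ndimage

    img = ndimage.gaussian_filter(rng.random((96, 96)), 1.0)
    yy, xx = np.mgrid[0:96, 0:96]
    img += 2.0 * np.exp(-((yy - 48) ** 2 + (xx - 40) ** 2) / 60.0)
    return img


@pytest.fixture(scope="session")
def scope():
    return Microscope()


@pytest.fixture(scope="session")
def phantom(scope):
    return default_phantom(scope)
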