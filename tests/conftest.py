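import numpy as np
import pytest

from sonomass import phantom as ph


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_region_image():
    """Noiseless two-level image: left half 40, right half 200."""
    img = np.zeros((64, 64), dtype=np.uint8)
    img[:, :32] = 40
    img[:, 32:] = 200
    return img


@pytest.fixture(scope="session")
def speckled_two_region(rng):
    """Two-level image with mild multiplicative speckle."""
    clean = np.zeros((64, 64))
    clean[:, :32] = 40.0
    clean[:, 32:] = 200.0
    noise = rng.gamma(shape=60.0, scale=1.0 / 60.0, size=clean.shape)
    return np.clip(np.rint(clean * noise), 0, 255).astype(np.uint8)


@pytest.fixture(scope="session")
def benign_phantom():
    return ph.generate_phantom(ph.PhantomSpec(class_label="benign", seed=7))


@pytest.fixture(scope="session")
def malignant_phantom():
    return ph.generate_phantom(ph.PhantomSpec(class_label="malignant", seed=3))
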