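import numpy as np
import pytest
from scipy import ndimage as ndi

from lipnet import skeletonize_binary


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_blob(seed: int, shape=(48, 48), density: float = 0.6) -> np.ndarray:
    """Random blobby foreground used for skeletonization stress tests."""
    r = np.random.default_rng(seed)
    img = r.random(shape) > density
    return ndi.binary_closing(img, structure=np.ones((3, 3)))


def random_thin_skeleton(seed: int, shape=(48, 48)) -> np.ndarray:
    """A unit-width skeleton obtained by thinning a random blob."""
    return skeletonize_binary(random_blob(seed, shape))


@pytest.fixture
def plus_shape():
    # center at (3, 3) with four orthogonal arms of 2 px; under
    # 8-connectivity the center and the four inner arm pixels are mutually
    # adjacent and form one junction component, the tips are end-points
    sk = np.zeros((7, 7), dtype=bool)
    sk[3, 1:6] = True
    sk[1:6, 3] = True
    return sk


@pytest.fixture
def five_px_line():
    sk = np.zeros((3, 7), dtype=bool)
    sk[1, 1:6] = True
    return sk


@pytest.fixture
def t_shape():
    sk = np.zeros((4, 4), dtype=bool)
    for r, c in [(0, 0), (0, 1), (0, 2), (1, 1), (2, 1)]:
        sk[r, c] = True
    return sk


@pytest.fixture
def diamond_cycle():
    sk = np.zeros((4, 4), dtype=bool)
    for r, c in [(0, 1), (1, 0), (1, 2), (2, 1)]:
        sk[r, c] = True
    return sk
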