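import numpy as np
import pytest

from shapeqtl import SCHEME_PRESETS, ShapeSet, generate_leaf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wild_leaf():
    """A lobed wild-type silhouette on a 32-pixel grid."""
    return generate_leaf(SCHEME_PRESETS["big"][0], 32)


@pytest.fixture(scope="session")
def cultivar_leaf():
    return generate_leaf(SCHEME_PRESETS["big"][1], 32)


@pytest.fixture
def leaf_pair(wild_leaf, cultivar_leaf):
    return ShapeSet([wild_leaf, cultivar_leaf], ["wild", "cultivar"])


def random_binary_image(rng, L, p=0.4):
    """A random binary image guaranteed to contain both pixel classes."""
    while True:
        img = (rng.random((L, L)) < p).astype(np.uint8)
        if 0 < img.sum() < img.size:
            return img
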