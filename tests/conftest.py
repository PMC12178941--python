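import numpy as np
import pytest

from pmvnet.motifs import build_catalog
from pmvnet.synthetic import generate_atlas
from pmvnet.types import AtlasGeometry


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def small_atlas() -> AtlasGeometry:
    """12-region seeded atlas shared by the fast unit tests."""
    return generate_atlas(12, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_edge_labels(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric edge-class matrix (values 0..3, diagonal -1)."""
    upper = rng.integers(0, 4, size=(n, n))
    labels = np.triu(upper, k=1)
    labels = labels + labels.T
    np.fill_diagonal(labels, -1)
    return labels
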