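import numpy as np
import pytest

from adaptsel import SyntheticSpec, generate, normalize_minmax
from adaptsel.chemspace import ChemSpace, DescriptorTable, distance_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Tiny normalized table with a known linear endpoint structure."""
    table, y, truth = generate(
        SyntheticSpec(n_compounds=60, n_dense=2, n_sparse=18, seed=3)
    )
    return normalize_minmax(table), y, truth


def make_space(points) -> ChemSpace:
    points = np.asarray(points, dtype=float)
    return ChemSpace(points=points, DM=distance_matrix(points))


@pytest.fixture
def cloud_space(rng):
    """A 20-point random cloud in 3 dimensions."""
    return make_space(rng.normal(size=(20, 3)))
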