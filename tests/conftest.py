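import numpy as np
import pytest

from lobulesim.params import ModelParams


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_lattice(rng, shape=(20, 20), n_cells=6):
    """Random multi-cell lattice plus consistent caches for CPM tests."""
    from lobulesim import geometry as geo

    grid = rng.integers(0, n_cells + 1, size=shape).astype(np.int32)
    klass = np.zeros(n_cells + 1, dtype=np.int8)
    klass[1:] = rng.integers(2, 7, size=n_cells)  # cell classes only
    area = np.bincount(grid.ravel(), minlength=n_cells + 1).astype(np.int64)
    target = rng.uniform(5, 40, size=n_cells + 1)
    target[0] = 0.0
    return grid, klass, area, target
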