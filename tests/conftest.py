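import numpy as np
import pytest

from argogaps import make_grid, cell_areas


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def areas(grid):
    return cell_areas(grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)
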