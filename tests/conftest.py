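import numpy as np
import pytest

from spatialepi import (make_grid_frame, queen_adjacency, row_standardize,
                        shared_border_adjacency)


@pytest.fixture(scope="session")
def grid_2x2():
    return make_grid_frame(2, 2)


@pytest.fixture(scope="session")
def grid_3x3():
    return make_grid_frame(3, 3)


@pytest.fixture(scope="session")
def grid_8x8():
    return make_grid_frame(8, 8)


@pytest.fixture(scope="session")
def grid_10x10():
    return make_grid_frame(10, 10)


@pytest.fixture(scope="session")
def rook_2x2(grid_2x2):
    """2x2 lattice with shared-border (rook) contiguity: a 4-cycle."""
    return shared_border_adjacency(grid_2x2)


@pytest.fixture(scope="session")
def queen_8x8(grid_8x8):
    return queen_adjacency(grid_8x8)


@pytest.fixture(scope="session")
def queen_8x8_std(queen_8x8):
    return row_standardize(queen_8x8)


@pytest.fixture(scope="session")
def queen_10x10_std(grid_10x10):
    return row_standardize(queen_adjacency(grid_10x10))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
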