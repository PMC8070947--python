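import numpy as np
import pytest

from islevi import CategoricalRaster, Grid, Raster, RegionMask


def make_grid(n_rows=10, n_cols=None, cell=30.0):
    n_cols = n_rows if n_cols is None else n_cols
    return Grid(n_rows, n_cols, cell, origin=(0.0, n_rows * cell))


def make_raster(values, grid=None, valid=None):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = make_grid(values.shape[0], values.shape[1])
    return Raster(grid, values, valid)


def make_cat(levels, n_states, grid=None, valid=None):
    levels = np.asarray(levels)
    if grid is None:
        grid = make_grid(levels.shape[0], levels.shape[1])
    return CategoricalRaster(grid, levels, n_states, valid)


def full_mask(grid):
    return RegionMask(grid, np.ones(grid.shape, dtype=bool))


@pytest.fixture
def grid10():
    return make_grid(10)


@pytest.fixture
def domain10(grid10):
    return full_mask(grid10)
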