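import numpy as np
import pytest

import agrozone as az


@pytest.fixture
def fixture6():
    """The hand-computed 6x6 worked example."""
    return az.worked_fixture()


@pytest.fixture
def small_grid():
    return az.GridSpec(n_rows=4, n_cols=6, x_min=0.0, y_max=40.0, cell_size=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def constant_monthly(grid, value, n=12, nodata=-9999.0):
    """12 aligned constant rasters."""
    return [
        az.Raster(grid, np.full(grid.shape, float(v)), nodata=nodata)
        for v in (value if hasattr(value, "__len__") else [value] * n)
    ]


@pytest.fixture
def banded_world():
    """Three-band synthetic climate on a coarse global grid, stratified."""
    grid = az.GridSpec(n_rows=36, n_cols=72, x_min=-180.0, y_max=90.0, cell_size=5.0)
    stack = az.gen_climate(az.SynthClimateParams(grid=grid, seed=7, noise_sd=0.5), n_bands=3)
    params = az.StratifyParams(n_strata=3, n_zones=3, seed=7)
    strata = az.group_zones(az.cluster_strata(az.compute_variables(stack), params), params)
    return grid, stack, strata
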