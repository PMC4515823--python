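import numpy as np
import pytest

from palmx.grid import Grid
from palmx.scenarios import BASELINE, ScenarioKey
from palmx.world import (ClimateLayerSet, LAYER_NAMES, default_config,
                         generate_climate)


@pytest.fixture(scope="session")
def small_world():
    """A 24x24 world with a reduced factorial, shared by read-only tests."""
    return default_config(24, 24, seed=7, n_gcm=2, n_sres=2)


@pytest.fixture(scope="session")
def small_baseline(small_world):
    return generate_climate(small_world, ScenarioKey(BASELINE))


def make_climate(values_per_layer, grid=None, key=None):
    """Build a ClimateLayerSet from explicit per-layer constants or arrays."""
    arrays = {}
    for name, v in zip(LAYER_NAMES, values_per_layer):
        arr = np.asarray(v, dtype=float)
        arrays[name] = arr
    if grid is None:
        shape = next(iter(arrays.values())).shape
        grid = Grid(shape[0], shape[1], 10.0)
    for name in LAYER_NAMES:
        if arrays[name].shape != grid.shape:
            arrays[name] = np.full(grid.shape, float(values_per_layer[
                LAYER_NAMES.index(name)]))
    return ClimateLayerSet(grid=grid, key=key or ScenarioKey(BASELINE),
                           layers=arrays)
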