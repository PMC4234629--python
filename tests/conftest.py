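import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from swordgrid import synth
from swordgrid.environment import Environment
from swordgrid.grid import Grid


@pytest.fixture(scope="session")
def env_small() -> Environment:
    """Small synthetic ocean shared by unit tests (50-km cells)."""
    return synth.make_environment(resolution_km=50.0, seed=3)


@pytest.fixture(scope="session")
def open_planar_grid() -> Grid:
    """All-water planar basin for idealized dynamics tests."""
    return Grid.regular((-10.0, -10.0, 10.0, 10.0), 55.0, planar=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def flat_env(grid: Grid, sst_value: float = 20.0) -> Environment:
    """Environment with spatially constant SST (uninformative reference)."""
    return Environment(grid, np.full((12, grid.nlat, grid.nlon), sst_value))


@pytest.fixture()
def toy_env(open_planar_grid: Grid) -> Environment:
    return flat_env(open_planar_grid)
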