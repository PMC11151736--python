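import time

import numpy as np
import pytest

from stormfate.driver import run_simulation
from stormfate.grid_io import SimulationConfig
from stormfate.raster import RasterGrid
from stormfate.synth import SynthSpec, build_watershed, make_weather


@pytest.fixture(scope="session")
def demo_spec() -> SynthSpec:
    """The standard demo-year watershed spec (100x100 cells at 5 m, seed 0)."""
    return SynthSpec(seed=0)


@pytest.fixture(scope="session")
def demo_watershed(demo_spec):
    return build_watershed(demo_spec)


@pytest.fixture(scope="session")
def demo_weather(demo_spec):
    return make_weather(demo_spec, 2020)


@pytest.fixture(scope="session")
def demo_run(demo_watershed, demo_weather):
    """Full demo-year simulation plus its wall-clock runtime (seconds)."""
    t0 = time.monotonic()
    result = run_simulation(demo_watershed, demo_weather, SimulationConfig())
    return result, time.monotonic() - t0


def column_dem(n_rows: int, cell_size: float = 5.0, drop: float = 1.0) -> RasterGrid:
    """Single-column DEM tilted due south (row n-1 lowest)."""
    z = (np.arange(n_rows)[::-1] * drop).reshape(n_rows, 1).astype(float)
    return RasterGrid(values=z, cell_size=cell_size)


def south_plane(n: int = 5, cell_size: float = 5.0, drop: float = 1.0) -> RasterGrid:
    """Square DEM tilted due south."""
    z = np.repeat((np.arange(n)[::-1] * drop)[:, None], n, axis=1).astype(float)
    return RasterGrid(values=z, cell_size=cell_size)


def twin_valley_dem(cell_size: float = 5.0) -> RasterGrid:
    """5x5 DEM with two parallel south-draining valleys (axes at columns 1
    and 3) separated by the ridge column 2."""
    z = np.zeros((5, 5))
    for r in range(5):
        for c in range(5):
            axis_dist = abs(c - 1) if c <= 2 else abs(c - 3)
            if c == 2:
                axis_dist = 1
            z[r, c] = (4 - r) * 2.0 + axis_dist
    return RasterGrid(values=z, cell_size=cell_size)
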