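import numpy as np
import pytest

from ricenest.grids import DEFAULT_SCHEME, Grid, PointPattern
from ricenest.synth import (
    generate_band_stack,
    generate_dem,
    generate_sample_plots,
    generate_true_landcover,
)
from ricenest.terrain import classify_elevation, classify_terrain_position


@pytest.fixture(scope="session")
def small_landscape():
    """A 64x64 synthetic landscape shared by the slower integration tests."""
    ss = np.random.SeedSequence(42).spawn(4)
    dem = generate_dem(64, 64, 100.0, seed=ss[0])
    terr = classify_terrain_position(dem, 8)
    elev = classify_elevation(dem)
    truth = generate_true_landcover(dem, terr.grid, seed=ss[1])
    bands = generate_band_stack(truth, seed=ss[2])
    plots = generate_sample_plots(truth, 768, seed=ss[3])
    return {"dem": dem, "terrain": terr, "elevation": elev, "truth": truth,
            "bands": bands, "plots": plots, "scheme": DEFAULT_SCHEME}


@pytest.fixture
def unit_window():
    return (0.0, 0.0, 1.0, 1.0)


def uniform_pattern(n, window, rng):
    xmin, ymin, xmax, ymax = window
    pts = np.column_stack([rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)])
    return PointPattern(pts, window)


@pytest.fixture
def make_uniform_pattern():
    return uniform_pattern
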