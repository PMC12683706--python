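import numpy as np
import pandas as pd
import pytest

from escapes.escape_map import compute_hri, compute_iei
from escapes.habitat import edge_area
from escapes.mixing import TEF, SourceSignature
from escapes.raster import MARSH, OTHER, WATER, Raster
from escapes.simulate import LandscapeConfig, default_sources, make_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """120x120 patchy marsh/water landscape at 10 m cells."""
    return make_landscape(LandscapeConfig(width=120, height=120, marsh_fraction=0.3, seed=11))


@pytest.fixture(scope="session")
def small_escape(small_landscape):
    hab, chl = small_landscape
    edge = edge_area(hab)
    iei = compute_iei(hab, chl, edge, (0.68, 0.23, 0.09), n_points=150, seed=3)
    return compute_hri(hab, chl, edge, iei, unit=200.0)


@pytest.fixture(scope="session")
def sources():
    return default_sources()


@pytest.fixture(scope="session")
def tef_zero():
    return TEF(mean=(0.0, 0.0), sd=(0.0, 0.0))


def all_water(n=30, chl_value=0.5, cell_size=10.0):
    hab = Raster(np.full((n, n), WATER), cell_size=cell_size)
    chl = Raster(np.full((n, n), float(chl_value)), cell_size=cell_size)
    return hab, chl


@pytest.fixture
def water_landscape():
    return all_water()
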