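import numpy as np
import pytest

from grainsdm.grid import CATEGORICAL, CONTINUOUS, Grid
from grainsdm.landscape import (BCV, BPV, LandscapeBundle, LandscapeParams,
                                SpeciesParams, generate_landscape,
                                true_suitability)


@pytest.fixture(scope="session")
def bundle80():
    """Small training landscape shared across tests (80x80 at 50 m)."""
    return generate_landscape(LandscapeParams(extent_cells=(80, 80), seed=1))


@pytest.fixture(scope="session")
def species():
    return SpeciesParams()


@pytest.fixture(scope="session")
def truth80(bundle80, species):
    return true_suitability(bundle80, species)


def make_bundle(altitude, slope, aspect, landcover, dist_water, cell_size=50.0):
    """Hand-built aligned bundle from raw arrays (for formula checks)."""
    geo = dict(origin=(0.0, 0.0), cell_size=cell_size)
    grids = {
        "altitude": Grid(np.asarray(altitude, float), kind=CONTINUOUS, **geo),
        "slope": Grid(np.asarray(slope, float), kind=CONTINUOUS, **geo),
        "aspect": Grid(np.asarray(aspect, float), kind=CONTINUOUS, **geo),
        "landcover": Grid(np.asarray(landcover, float), kind=CATEGORICAL, **geo),
        "dist_water": Grid(np.asarray(dist_water, float), kind=CONTINUOUS, **geo),
    }
    cats = {n: BPV for n in grids}
    return LandscapeBundle(grids, cats)


@pytest.fixture
def tiny_config():
    """Fast full-study configuration for pipeline tests."""
    from grainsdm.pipeline import StudyConfig
    return StudyConfig(
        landscape_train=LandscapeParams(extent_cells=(80, 80)),
        species=SpeciesParams(n_presences=60),
        n_rep=2, n_background=400, n_transfer_presences=50, master_seed=11)
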