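import numpy as np
import pytest

import nichecast as nc
from nichecast.grids import locate_cells


@pytest.fixture(scope="session")
def world():
    """Default synthetic study system (seed 1), occurrences located."""
    grid, niche, suit, occ = nc.default_world(seed=1)
    occ = locate_cells(occ, grid.geometry)
    return {"grid": grid, "niche": niche, "suit": suit, "occ": occ}


@pytest.fixture(scope="session")
def small_world():
    """Reduced world for fast fitting tests."""
    grid, niche, suit, occ = nc.default_world(seed=7, n_rows=50, n_cols=50,
                                              n_presences=120)
    occ = locate_cells(occ, grid.geometry)
    return {"grid": grid, "niche": niche, "suit": suit, "occ": occ}


@pytest.fixture(scope="session")
def niche_fit(world):
    """One full-presence fit on the three informative variables."""
    model = nc.MaxEnt.from_env_grid(world["grid"], world["occ"],
                                    variables=["temp_cold_q", "prec_wet_m", "prec_dry_m"])
    return model.fit(seed=1)


@pytest.fixture(scope="session")
def reference_tables():
    return nc.load_reference_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
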