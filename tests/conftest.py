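import numpy as np
import pytest
from hypothesis import settings

from woodhaul import (
    DemographyParams,
    GridSpec,
    Landscape,
    SpeciesParams,
    SuitabilityField,
    TreeTable,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return GridSpec(nx=10, ny=10, cell_km=2.0, central_places=((5, 5),))


@pytest.fixture
def uniform_suit(small_grid):
    return SuitabilityField(
        np.ones((small_grid.nx, small_grid.ny)), 0.0, 0
    )


@pytest.fixture
def fast_params():
    """Small, fast demography for fixtures (short-lived, quick-growing)."""
    sp = dict(growth_rate=0.1, inflection_age=30.0, max_age=200)
    return DemographyParams(
        pinyon=SpeciesParams(max_biomass_kg=500.0, recruitment_rate=1.0, **sp),
        juniper=SpeciesParams(max_biomass_kg=400.0, recruitment_rate=1.0, **sp),
    )


def make_landscape(grid, stems):
    """Hand-built landscape from (species_code, age, biomass, alive, x, y) rows."""
    suit = SuitabilityField(np.ones((grid.nx, grid.ny)), 0.0, 0)
    if stems:
        sp, age, b, alive, xs, ys = zip(*stems)
        trees = TreeTable(
            species=np.array(sp, np.uint8),
            age=np.array(age, np.int32),
            biomass=np.array(b, np.float64),
            alive=np.array(alive, bool),
            cell=np.array([grid.cell_id(x, y) for x, y in zip(xs, ys)], np.int64),
        )
    else:
        trees = TreeTable.empty()
    return Landscape(grid=grid, suitability=suit, trees=trees)
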