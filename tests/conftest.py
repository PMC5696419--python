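import numpy as np
import pytest

from sdmcascade import (
    DomainGrid,
    MonthlyClimate,
    VirtualSpecies,
    binarize_presence,
    make_monthly_climate,
    make_predictor_stack,
    make_topography,
    sample_species_occurrence,
)


@pytest.fixture(scope="session")
def grid():
    return DomainGrid(n_rows=20, n_cols=20, cell_size=0.25)


@pytest.fixture(scope="session")
def elevation(grid):
    return make_topography(grid, seed=7, relief=2000.0, fine_factor=4)


@pytest.fixture(scope="session")
def climate(grid, elevation):
    return make_monthly_climate(grid, elevation, seed=11)


@pytest.fixture(scope="session")
def stack(grid, elevation, climate):
    return make_predictor_stack(climate, elevation, grid)


@pytest.fixture(scope="session")
def cold_species():
    """Noise-free virtual species with a single informative predictor (bio1)."""
    return VirtualSpecies(
        name="cold",
        response_terms=(("bio1", 5.0, 3.0, 8.0),),
        baseline_prevalence=0.3,
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def cold_layer(cold_species, stack):
    frac, truth = sample_species_occurrence(cold_species, stack, seed=3)
    layer = binarize_presence(frac, 2.0, species=cold_species.name)
    return layer, truth


def random_climate(rng, shape=(4, 4)):
    """Random but physically ordered 12-month climate for property tests."""
    tmean = rng.normal(10, 8, size=(12, *shape))
    half = np.abs(rng.normal(4, 1, size=(12, *shape)))
    prec = np.abs(rng.normal(60, 40, size=(12, *shape)))
    return MonthlyClimate(tmin=tmean - half, tmean=tmean, tmax=tmean + half, prec=prec)
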