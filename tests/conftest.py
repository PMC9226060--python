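import numpy as np
import pytest

from maculamap.geometry import (
    assign_units,
    flip_vertical,
    make_10_2_pattern,
    make_grid,
)
from maculamap.synth import CohortParams, LinkParams, simulate_cohort


@pytest.fixture(scope="session")
def pattern():
    return make_10_2_pattern()


@pytest.fixture(scope="session")
def retinal_pattern(pattern):
    return flip_vertical(pattern)


@pytest.fixture(scope="session")
def cma_grid():
    return make_grid("CMA")


@pytest.fixture(scope="session")
def lma_grid():
    return make_grid("LMA")


@pytest.fixture(scope="session")
def cma_units(retinal_pattern, cma_grid):
    return assign_units(retinal_pattern, cma_grid, "CMA")


@pytest.fixture(scope="session")
def lma_units(retinal_pattern, lma_grid):
    return assign_units(retinal_pattern, lma_grid, "LMA")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-degenerate stratified cohort (9 patients, 3 healthy)."""
    return simulate_cohort(9, 3, seed=17)


@pytest.fixture(scope="session")
def quiet_params():
    """Noiseless, jitter-free, displacement-off simulator parameters."""
    return CohortParams(
        thickness_noise_um=0.0,
        link=LinkParams(noise_db_sd=0.0, jitter_sd_deg=0.0, displacement_on=False),
        fobmo_mean_deg=0.0,
        fobmo_sd_deg=0.0,
    )
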