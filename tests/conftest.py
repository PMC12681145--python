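"""Shared fixtures: one small synthetic world reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from habshift.bioclim import climatological_stack, default_registry
from habshift.grid import GridSpec
from habshift.sampling import select_background
from habshift.synthetic import (calibrate_intercept, default_truth_spec,
                                generate_climate, generate_landuse,
                                generate_sea_mask, generate_species_map)

SEED = 1


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """20 x 20 cells at 0.5 degrees."""
    return GridSpec(-5.0, 5.0, 35.0, 45.0, 0.5)


@pytest.fixture(scope="session")
def climate_small(small_grid):
    return generate_climate(small_grid, (1970, 2002), trend=0.4, seed=SEED)


@pytest.fixture(scope="session")
def landuse_small(small_grid):
    return generate_landuse(small_grid, (1970, 2002), drift_rate=0.02,
                            seed=SEED)


@pytest.fixture(scope="session")
def landmask_small(small_grid):
    return generate_sea_mask(small_grid, seed=SEED, sea_fraction=0.2)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def stack_2002(climate_small, landuse_small, registry, landmask_small):
    return climatological_stack(climate_small, landuse_small, 2002, registry,
                                mask=landmask_small)


@pytest.fixture(scope="session")
def truth_small(stack_2002):
    return calibrate_intercept(stack_2002, default_truth_spec(),
                               target_prevalence=0.4)


@pytest.fixture(scope="session")
def prob_map(stack_2002, truth_small, landmask_small):
    return generate_species_map(stack_2002, truth_small, noise_sd=0.0,
                                seed=SEED, mask=landmask_small)


@pytest.fixture(scope="session")
def sample_random(prob_map, stack_2002):
    return select_background(prob_map, stack_2002, "random", n_presence=100,
                             n_absence=100, seed=3)
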