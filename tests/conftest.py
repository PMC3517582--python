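"""Shared fixtures: small synthetic studies and toy grids/trees."""

from __future__ import annotations

import numpy as np
import pytest

from paleoniche.bioclim import EnvelopeModel
from paleoniche.geodata import ClimateLayer, ClimateScenario
from paleoniche.phylo import DatedTree
from paleoniche.synthetic import SimulationConfig, generate_study


def make_scenario(
    rng: np.random.Generator,
    shape=(20, 20),
    variables=("temp", "sd_temp", "precip_summer", "precip_winter"),
    name="present",
    age_ma=0.0,
    nodata_frac=0.0,
) -> ClimateScenario:
    """Random co-registered scenario; optional nodata speckle."""
    layers = []
    for var in variables:
        grid = rng.uniform(-10, 10, size=shape)
        if nodata_frac > 0:
            mask = rng.random(shape) < nodata_frac
            grid[mask] = -9999.0
        layers.append(
            ClimateLayer(var, grid, origin=(-120.0, 45.0), cell_size=0.5,
                         nodata_value=-9999.0)
        )
    return ClimateScenario(name=name, age_ma=age_ma, layers=layers)


def random_envelope(rng: np.random.Generator, variables) -> EnvelopeModel:
    bounds = {}
    for var in variables:
        a, b = sorted(rng.uniform(-10, 10, size=2))
        bounds[var] = (float(a), float(b))
    return EnvelopeModel("random", bounds)


@pytest.fixture(scope="session")
def small_study():
    """8-tip synthetic study used by several unit tests."""
    cfg = SimulationConfig(
        n_tips=8, grid_shape=(30, 30), n_occurrences_per_tip=40, seed=11
    )
    return generate_study(cfg)


@pytest.fixture
def three_tip_tree() -> DatedTree:
    return DatedTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
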