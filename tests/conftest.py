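"""Shared fixtures: small synthetic worlds generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from antdiv import synthetic_world as sw
from antdiv.grid import GridSpec


def make_flat_grid(n_rows: int = 20, n_cols: int = 40,
                   resolution_arcmin: float = 60.0,
                   lat_center: float = 0.0) -> GridSpec:
    """All-land grid centered on a latitude band (no exclusion zone)."""
    half_h = n_rows * resolution_arcmin / 120.0
    half_w = n_cols * resolution_arcmin / 120.0
    return GridSpec(resolution_arcmin, -half_w, half_w,
                    lat_center - half_h, lat_center + half_h,
                    land_mask=np.ones((n_rows, n_cols), bool),
                    exclusion_mask=np.zeros((n_rows, n_cols), bool))


@pytest.fixture(scope="session")
def flat_grid() -> GridSpec:
    return make_flat_grid()


@pytest.fixture(scope="session")
def world():
    """Small synthetic world shared across modules (seeded, ~2400 cells)."""
    grid = sw.generate_grid(resolution_arcmin=120.0, lon_min=-60, lon_max=60,
                            lat_min=-40, lat_max=40, land_fraction=0.5, seed=11)
    env = sw.generate_environment(grid, 3, seed=12)
    gaz = sw.build_gazetteer(grid)
    bias = sw.generate_bias_field(grid, seed=13)
    pool = sw.generate_species_pool(env, 30, seed=14)
    return dict(grid=grid, env=env, gazetteer=gaz, bias=bias, pool=pool)


@pytest.fixture(scope="session")
def noisy_records(world):
    return sw.simulate_collection(world["pool"], world["bias"], effort=6.0,
                                  noise=sw.NoiseConfig(), gazetteer=world["gazetteer"],
                                  seed=21)


@pytest.fixture(scope="session")
def clean_records(world):
    return sw.simulate_collection(world["pool"], world["bias"], effort=6.0,
                                  noise=sw.NoiseConfig.zero(),
                                  gazetteer=world["gazetteer"], seed=22)
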