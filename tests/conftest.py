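"""Shared fixtures: small analytic grids, a compact synthetic basin and the
full-scale demo run used by the acceptance checks."""

from __future__ import annotations

import numpy as np
import pytest

from metaconn import (
    Grid,
    SyntheticBasinSpec,
    assign_cells_to_sectors,
    build_sectors,
    make_basin,
)
from metaconn.geometry import EARTH_RADIUS_KM, LocalProjection

KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


def km_grid(x_km: np.ndarray, y_km: np.ndarray, sea=None, lat0: float = 0.0) -> Grid:
    """Grid whose cell centers sit (to within a ppm-level cos(lat) factor)
    at the requested km coordinates; handy for analytic fixtures."""
    lon = np.asarray(x_km, float) / (KM_PER_DEG * np.cos(np.deg2rad(lat0)))
    lat = lat0 + np.asarray(y_km, float) / KM_PER_DEG
    if sea is None:
        sea = np.ones((len(y_km), len(x_km)), dtype=bool)
    return Grid(lon, lat, sea)


@pytest.fixture()
def open_sea_grid():
    """51 x 51 all-sea grid with ~2 km cells (open boundaries)."""
    return km_grid(np.arange(51) * 2.0, np.arange(51) * 2.0, lat0=40.0)


@pytest.fixture()
def small_basin():
    """Closed 200 x 250 km basin (10 km cells) with sectors and footprints."""
    spec = SyntheticBasinSpec(width_km=200.0, height_km=250.0, cell_km=10.0,
                              gyre_speed=0.1, noise_sd=0.0, seed=7)
    grid, coast = make_basin(spec)
    sectors = build_sectors(coast, 25.0, proj=grid.proj)
    assign_cells_to_sectors(grid, sectors, 30.0)
    return spec, grid, coast, sectors


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """The built-in cyclonic demo at full scale, run once per session.

    120 perimeter sectors, 4 species with dispersal durations 30/30/10/7
    days, 10^4 propagules per species per year over 3 years, fixed seed.
    """
    from metaconn.pipeline import default_demo_config, run_all

    out = tmp_path_factory.mktemp("demo")
    cfg = default_demo_config(output_dir=str(out), seed=0, n_particles=10_000)
    manifest = run_all(cfg)
    return cfg, out, manifest
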