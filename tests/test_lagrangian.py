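"""Release schedules, RK4 advection and fate classification."""

import numpy as np
import pandas as pd
import pytest

from metaconn import (
    SpeciesTraits,
    advect,
    build_habitat_mask,
    classify_fates,
    make_field_from_function,
    make_uniform_field,
    make_zero_field,
    release_schedule,
    simulate_species_year,
)
from metaconn.lagrangian import (
    OUTCOME_EXITED,
    OUTCOME_SETTLED,
    OUTCOME_UNSUITABLE,
    EndStates,
    ReleaseSet,
)

from conftest import km_grid


def _flat_habitat(grid, sectors, where=None):
    rng = np.ones_like(grid.sea_mask) if where is None else where
    depth = np.full(grid.sea_mask.shape, 10.0)
    return build_habitat_mask("sp", rng, depth, (0, 40), grid, sectors)


def _one_particle(grid, x_km, y_km, date="2003-01-01"):
    lon, lat = grid.proj.to_lonlat(x_km, y_km)
    return ReleaseSet(
        lon=np.atleast_1d(lon).astype(float), lat=np.atleast_1d(lat).astype(float),
        date=np.array([date], dtype="datetime64[D]"),
        source_sector=np.array([1]), year=2003, species="test",
    )


class TestSpeciesTraits:
    @pytest.mark.parametrize("window,days,depths", [
        ((0, 100), 10, (0, 40)),      # day-of-year below 1
        ((100, 50), 10, (0, 40)),     # end before start
        ((1, 100), 0, (0, 40)),       # no dispersing stage
        ((1, 100), 10, (40, 0)),      # inverted depth band
    ])
    def test_invalid_traits_rejected(self, window, days, depths):
        with pytest.raises(ValueError):
            SpeciesTraits("x", window, days, recruitment_depth_range=depths)


class TestReleaseSchedule:
    def test_counts_from_one_cell(self, small_basin):
        spec, grid, coast, sectors = small_basin
        lab = sectors.footprints
        iy, ix = [a[0] for a in np.where(lab == 5)], None
        cell = np.argwhere(lab == 5)[0]
        where = np.zeros_like(grid.sea_mask)
        where[cell[0], cell[1]] = True
        hab = _flat_habitat(grid, sectors, where)
        tr = SpeciesTraits("sp", (100, 109), 5.0)  # 10-day window
        rel = release_schedule(tr, hab, sectors, grid, 2003, n_per_cell_per_day=3, seed=1)
        assert rel.n == 30
        assert np.all(rel.source_sector == 5)
        # evenly spread over the 10 release days
        _, counts = np.unique(rel.date, return_counts=True)
        assert counts.tolist() == [3] * 10

    def test_counts_proportional_to_area(self, small_basin):
        spec, grid, coast, sectors = small_basin
        lab = sectors.footprints
        a_cells = np.argwhere(lab == 3)[:2]
        b_cells = np.argwhere(lab == 9)[:1]
        where = np.zeros_like(grid.sea_mask)
        for c in np.vstack([a_cells, b_cells]):
            where[c[0], c[1]] = True
        hab = _flat_habitat(grid, sectors, where)
        tr = SpeciesTraits("sp", (100, 100), 5.0)
        rel = release_schedule(tr, hab, sectors, grid, 2003, n_total=30,
                               placement="center", seed=0)
        assert rel.n == 30
        n3 = int(np.sum(rel.source_sector == 3))
        n9 = int(np.sum(rel.source_sector == 9))
        assert (n3, n9) == (20, 10)  # 2:1 cell (area) ratio, exact

    def test_same_seed_identical(self, small_basin):
        spec, grid, coast, sectors = small_basin
        hab = _flat_habitat(grid, sectors)
        tr = SpeciesTraits("sp", (100, 120), 5.0)
        a = release_schedule(tr, hab, sectors, grid, 2003, n_total=200, seed=42)
        b = release_schedule(tr, hab, sectors, grid, 2003, n_total=200, seed=42)
        np.testing.assert_array_equal(a.lon, b.lon)
        np.testing.assert_array_equal(a.lat, b.lat)
        np.testing.assert_array_equal(a.date, b.date)

    def test_empty_habitat_warns(self, small_basin):
        spec, grid, coast, sectors = small_basin
        hab = _flat_habitat(grid, sectors, np.zeros_like(grid.sea_mask))
        tr = SpeciesTraits("sp", (100, 120), 5.0)
        with pytest.warns(UserWarning, match="no suitable habitat"):
            rel = release_schedule(tr, hab, sectors, grid, 2003, n_total=10, seed=0)
        assert rel.n == 0

    def test_positions_inside_suitable_cells(self, small_basin):
        spec, grid, coast, sectors = small_basin
        hab = _flat_habitat(grid, sectors)
        tr = SpeciesTraits("sp", (100, 110), 5.0)
        rel = release_schedule(tr, hab, sectors, grid, 2003, n_total=500, seed=3)
        iy, ix = grid.cell_index(rel.lon, rel.lat)
        assert np.all(hab.suitable[iy, ix])
        np.testing.assert_array_equal(sectors.footprints[iy, ix], rel.source_sector)


class TestAdvect:
    def test_zero_field_keeps_position(self, open_sea_grid):
        f = make_zero_field(open_sea_grid, 3)
        rel = _one_particle(open_sea_grid, 50.0, 50.0)
        end = advect(rel, f, 2.0)
        np.testing.assert_allclose(end.lon, rel.lon)
        np.testing.assert_allclose(end.lat, rel.lat)
        assert not end.exited.any()

    def test_uniform_flow_analytic_displacement(self, open_sea_grid):
        # 0.1 m/s east for one day = 8.64 km
        f = make_uniform_field(0.1, 0.0, open_sea_grid, 3)
        rel = _one_particle(open_sea_grid, 10.0, 50.0)
        end = advect(rel, f, 1.0, dt_hours=1.0)
        x0, y0 = open_sea_grid.proj.to_km(rel.lon, rel.lat)
        x1, y1 = open_sea_grid.proj.to_km(end.lon, end.lat)
        np.testing.assert_allclose(x1 - x0, 8.64, rtol=1e-3)
        np.testing.assert_allclose(y1 - y0, 0.0, atol=1e-9)

    @pytest.fixture()
    def rotation(self):
        # solid-body rotation with a 10-day period around the grid center
        om = 2 * np.pi / 10.0  # rad/day
        grid = km_grid(np.arange(81) * 1.25, np.arange(81) * 1.25, lat0=40.0)

        def sb(X, Y):
            return -om * Y / 86.4, om * X / 86.4  # m/s so that km/day = om*r

        return grid, make_field_from_function(grid, sb, 12)

    def test_rotation_closes_orbit(self, rotation):
        grid, f = rotation
        rel = _one_particle(grid, 0.0, 20.0)
        end = advect(rel, f, 10.0, dt_hours=1.0)
        x1, y1 = grid.proj.to_km(end.lon, end.lat)
        err = np.hypot(x1 - 0.0, y1 - 20.0)[0]
        assert err < 0.01 * 20.0  # within 1% of the radius

    def test_halving_dt_barely_moves_endpoint(self, rotation):
        grid, f = rotation
        rel = _one_particle(grid, 0.0, 20.0)
        e1 = advect(rel, f, 10.0, dt_hours=1.0)
        e2 = advect(rel, f, 10.0, dt_hours=0.5)
        x1, y1 = grid.proj.to_km(e1.lon, e1.lat)
        x2, y2 = grid.proj.to_km(e2.lon, e2.lat)
        assert np.hypot(x1 - x2, y1 - y2)[0] < 1e-3  # km; RK4 convergence

    def test_bad_dt_and_short_field_error(self, open_sea_grid):
        f = make_zero_field(open_sea_grid, 2)
        rel = _one_particle(open_sea_grid, 50.0, 50.0)
        with pytest.raises(ValueError, match="dt_hours"):
            advect(rel, f, 1.0, dt_hours=0.0)
        with pytest.raises(ValueError, match="cover"):
            advect(rel, f, 10.0)

    def test_exit_through_open_boundary(self, open_sea_grid):
        # strong eastward flow pushes the particle past the grid edge
        f = make_uniform_field(0.5, 0.0, open_sea_grid, 5)
        rel = _one_particle(open_sea_grid, 95.0, 50.0)
        end = advect(rel, f, 3.0)
        assert end.exited.all()

    def test_diffusion_is_seeded_and_optional(self, open_sea_grid):
        f = make_zero_field(open_sea_grid, 3)
        rel = _one_particle(open_sea_grid, 50.0, 50.0)
        a = advect(rel, f, 2.0, diffusivity_m2_s=10.0, seed=5)
        b = advect(rel, f, 2.0, diffusivity_m2_s=10.0, seed=5)
        c = advect(rel, f, 2.0)
        np.testing.assert_array_equal(a.lon, b.lon)
        assert a.lon[0] != c.lon[0]  # diffusion actually moved it


class TestClassifyAndConservation:
    def test_fate_categories(self, small_basin):
        spec, grid, coast, sectors = small_basin
        hab = _flat_habitat(grid, sectors)
        # hand-build end states: settled in place / unsuitable / exited
        suitable_cell = np.argwhere(hab.suitable & (sectors.footprints > 0))[0]
        lon_s = float(grid.lon_centers[suitable_cell[1]])
        lat_s = float(grid.lat_centers[suitable_cell[0]])
        rel = ReleaseSet(
            lon=np.array([lon_s] * 3), lat=np.array([lat_s] * 3),
            date=np.array(["2003-01-01"] * 3, dtype="datetime64[D]"),
            source_sector=np.array([1, 1, 1]), year=2003, species="sp",
        )
        hab_partial = build_habitat_mask(
            "sp", np.ones_like(grid.sea_mask), np.full(grid.sea_mask.shape, 10.0),
            (0, 40), grid, sectors)
        hab_partial.suitable = hab_partial.suitable.copy()
        mid = np.argwhere(grid.sea_mask & (sectors.footprints == 0))
        interior = mid[0] if len(mid) else suitable_cell
        end = EndStates(
            lon=np.array([lon_s, float(grid.lon_centers[interior[1]]), lon_s]),
            lat=np.array([lat_s, float(grid.lat_centers[interior[0]]), lat_s]),
            exited=np.array([False, False, True]),
        )
        fates = classify_fates(rel, end, hab_partial, sectors, grid)
        assert fates.loc[0, "outcome"] == OUTCOME_SETTLED
        assert fates.loc[0, "sink_sector"] == sectors.footprints[suitable_cell[0], suitable_cell[1]]
        assert fates.loc[2, "outcome"] == OUTCOME_EXITED
        # particle 1 landed either outside any footprint or off-habitat
        assert fates.loc[1, "outcome"] in (OUTCOME_UNSUITABLE, OUTCOME_SETTLED)

    def test_pure_retention_in_still_water(self, small_basin):
        spec, grid, coast, sectors = small_basin
        from metaconn import make_zero_field

        hab = _flat_habitat(grid, sectors)
        f = make_zero_field(grid, 200)
        tr = SpeciesTraits("sp", (10, 30), 7.0)
        fates = simulate_species_year(tr, hab, sectors, grid, f, 2003,
                                      n_particles=300, seed=2)
        assert (fates["outcome"] == OUTCOME_SETTLED).all()
        np.testing.assert_array_equal(fates["sink_sector"], fates["source_sector"])

    def test_conservation_of_particles(self, small_basin):
        spec, grid, coast, sectors = small_basin
        from metaconn import make_gyre_field

        hab = _flat_habitat(grid, sectors)
        f = make_gyre_field(spec, 60)
        tr = SpeciesTraits("sp", (10, 30), 10.0)
        fates = simulate_species_year(tr, hab, sectors, grid, f, 2003,
                                      n_particles=1000, seed=3)
        counts = fates["outcome"].value_counts()
        assert counts.sum() == len(fates) == 1000
        assert set(counts.index) <= {OUTCOME_SETTLED, OUTCOME_UNSUITABLE, OUTCOME_EXITED}

    def test_simulation_is_deterministic(self, small_basin):
        spec, grid, coast, sectors = small_basin
        from metaconn import make_gyre_field

        hab = _flat_habitat(grid, sectors)
        f = make_gyre_field(spec, 60)
        tr = SpeciesTraits("sp", (10, 20), 5.0)
        a = simulate_species_year(tr, hab, sectors, grid, f, 2003, n_particles=200, seed=9)
        b = simulate_species_year(tr, hab, sectors, grid, f, 2003, n_particles=200, seed=9)
        pd.testing.assert_frame_equal(a, b)
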