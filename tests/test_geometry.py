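"""Sectorization, footprints, habitat masks and within-sea distances."""

import heapq

import numpy as np
import pytest

from metaconn import (
    SeaDistance,
    SyntheticBasinSpec,
    assign_cells_to_sectors,
    build_habitat_mask,
    build_sectors,
    make_basin,
    sea_distance,
)
from metaconn.geometry import LocalProjection, _min_dist_to_polyline

from conftest import KM_PER_DEG, km_grid


def straight_coast(length_km: float, n_pts: int = 2) -> np.ndarray:
    """Meridional polyline of exactly the given length (lat-degrees scale is
    projection-independent)."""
    lats = np.linspace(0.0, length_km / KM_PER_DEG, n_pts)
    return np.column_stack([np.zeros(n_pts), lats])


class TestBuildSectors:
    def test_3000_km_perimeter_gives_120_sectors(self):
        spec = SyntheticBasinSpec(width_km=700, height_km=800, cell_km=10)
        grid, coast = make_basin(spec)
        sectors = build_sectors(coast, 25.0, proj=grid.proj)
        assert sectors.n == 120
        assert sectors.closed
        np.testing.assert_allclose(sectors.total_length_km, 3000.0, rtol=1e-9)
        assert all(abs(s.length_km - 25.0) < 1e-6 for s in sectors.sectors)

    def test_single_segment_coastline(self):
        sectors = build_sectors(straight_coast(25.0), 25.0)
        assert sectors.n == 1
        assert sectors.sectors[0].id == 1
        np.testing.assert_allclose(sectors.sectors[0].length_km, 25.0, atol=1e-9)

    def test_terminal_remainder_becomes_short_sector(self):
        # 260 km at 25-km segments: 10 full sectors plus a 10-km terminal one
        sectors = build_sectors(straight_coast(260.0, n_pts=27), 25.0)
        assert sectors.n == 11
        lengths = [s.length_km for s in sectors.sectors]
        np.testing.assert_allclose(lengths[:10], 25.0, atol=1e-9)
        np.testing.assert_allclose(lengths[10], 10.0, atol=1e-9)
        assert [s.id for s in sectors.sectors] == list(range(1, 12))

    def test_degenerate_and_short_coastlines_error(self):
        degenerate = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="degenerate|zero-length"):
            build_sectors(degenerate, 25.0)
        with pytest.raises(ValueError, match="shorter than one segment"):
            build_sectors(straight_coast(10.0), 25.0)

    def test_region_breaks_partition_the_chain(self):
        coast = straight_coast(200.0, n_pts=21)
        sectors = build_sectors(coast, 25.0, region_breaks=[100.0])
        assert sectors.n == 8
        assert list(sectors.region_ids) == [1] * 4 + [2] * 4
        with pytest.raises(ValueError, match="on the coastline"):
            build_sectors(coast, 25.0, region_breaks=[250.0])


class TestFootprints:
    def test_cell_next_to_segment_midpoint(self, small_basin):
        spec, grid, coast, sectors = small_basin
        sec = sectors.sectors[6]
        # cell nearest the midpoint of sector 7's own segment
        iy, ix = grid.cell_index(sec.midpoint[0], sec.midpoint[1])
        iy2, ix2 = np.where(grid.sea_mask)
        # nearest *sea* cell to that midpoint
        d2 = (iy2 - iy) ** 2 + (ix2 - ix) ** 2
        j = np.argmin(d2)
        assert sectors.footprints[iy2[j], ix2[j]] == 7

    def test_equidistant_cell_goes_to_lower_id(self):
        # straight coast split into 4 sectors; a cell whose nearest coast
        # point is the shared endpoint of sectors 3 and 4 ties exactly
        coast = straight_coast(100.0, n_pts=2)
        sectors = build_sectors(coast, 25.0)
        y = np.arange(5.0, 100.0, 10.0)
        x = np.arange(5.0, 50.0, 10.0)
        grid = km_grid(x, y)
        lab = assign_cells_to_sectors(grid, sectors, max_coastal_distance_km=200.0)
        # cell center (x=5, y=75) km: its nearest point on both sector 3
        # ([50, 75]) and sector 4 ([75, 100]) is the shared vertex y = 75
        iy = int(np.argmin(np.abs(y - 75.0)))
        ix = int(np.argmin(np.abs(x - 5.0)))
        assert lab[iy, ix] == 3

    def test_footprints_match_brute_force_nearest_segment(self, small_basin):
        spec, grid, coast, sectors = small_basin
        band = 30.0
        lab = sectors.footprints
        X, Y = np.meshgrid(grid.x_km, grid.y_km)
        # exhaustive oracle: per cell, scan every sector's polyline
        expect = np.zeros_like(lab)
        for iy in range(grid.n_lat):
            for ix in range(grid.n_lon):
                if not grid.sea_mask[iy, ix]:
                    continue
                best, arg = np.inf, 0
                for s in sectors.sectors:
                    vx, vy = grid.proj.to_km(s.vertices[:, 0], s.vertices[:, 1])
                    d = _min_dist_to_polyline(
                        np.array([X[iy, ix]]), np.array([Y[iy, ix]]),
                        np.column_stack([vx, vy]))[0]
                    if d < best - 1e-9:
                        best, arg = d, s.id
                expect[iy, ix] = arg if best <= band else 0
        np.testing.assert_array_equal(lab, expect)

    def test_footprints_are_disjoint_partition(self, small_basin):
        spec, grid, coast, sectors = small_basin
        lab = sectors.footprints
        assert lab.shape == grid.sea_mask.shape
        assert not np.any(lab[~grid.sea_mask])  # land never assigned
        assert set(np.unique(lab)) <= set(range(sectors.n + 1))


class TestHabitatMask:
    def test_full_range_shallow_depth_equals_sea(self, small_basin):
        spec, grid, coast, sectors = small_basin
        rng = np.ones_like(grid.sea_mask)
        depth = np.full(grid.sea_mask.shape, 10.0)
        hm = build_habitat_mask("sp", rng, depth, (0, 40), grid, sectors)
        np.testing.assert_array_equal(hm.suitable, grid.sea_mask)

    def test_unmatchable_depth_band_empties_mask(self, small_basin):
        spec, grid, coast, sectors = small_basin
        hm = build_habitat_mask("sp", np.ones_like(grid.sea_mask),
                                np.full(grid.sea_mask.shape, 10.0), (5, 5), grid, sectors)
        assert not hm.suitable.any()
        assert np.all(hm.sector_area_km2 == 0)

    def test_inverted_depth_range_errors(self, small_basin):
        spec, grid, coast, sectors = small_basin
        with pytest.raises(ValueError, match="inverted"):
            build_habitat_mask("sp", np.ones_like(grid.sea_mask),
                               np.zeros(grid.sea_mask.shape), (40, 0), grid, sectors)

    def test_checkerboard_areas_match_cell_enumeration(self, small_basin):
        spec, grid, coast, sectors = small_basin
        iy, ix = np.meshgrid(np.arange(grid.n_lat), np.arange(grid.n_lon), indexing="ij")
        checker = (iy + ix) % 2 == 0
        hm = build_habitat_mask("sp", checker, np.full(grid.sea_mask.shape, 10.0),
                                (0, 40), grid, sectors)
        lab = sectors.footprints
        for k in range(1, sectors.n + 1):
            n_cells = int(np.sum(hm.suitable & (lab == k)))
            np.testing.assert_allclose(hm.sector_area_km2[k - 1],
                                       n_cells * grid.cell_area_km2)
        total = np.sum(hm.suitable & (lab > 0)) * grid.cell_area_km2
        np.testing.assert_allclose(hm.sector_area_km2.sum(), total)


def _dijkstra_oracle(sea: np.ndarray, dx: float, dy: float, src, dst) -> float:
    """Plain heapq Dijkstra on the explicit 8-connected cell graph."""
    ny, nx = sea.shape
    dist = {src: 0.0}
    pq = [(0.0, src)]
    moves = [(0, 1, dx), (0, -1, dx), (1, 0, dy), (-1, 0, dy),
             (1, 1, np.hypot(dx, dy)), (1, -1, np.hypot(dx, dy)),
             (-1, 1, np.hypot(dx, dy)), (-1, -1, np.hypot(dx, dy))]
    while pq:
        d, (i, j) = heapq.heappop(pq)
        if (i, j) == dst:
            return d
        if d > dist.get((i, j), np.inf):
            continue
        for di, dj, w in moves:
            a, b = i + di, j + dj
            if 0 <= a < ny and 0 <= b < nx and sea[a, b]:
                nd = d + w
                if nd < dist.get((a, b), np.inf):
                    dist[(a, b)] = nd
                    heapq.heappush(pq, (nd, (a, b)))
    return np.inf


class TestSeaDistance:
    def test_zero_for_identical_points(self, open_sea_grid):
        g = open_sea_grid
        p = (float(g.lon_centers[10]), float(g.lat_centers[10]))
        assert sea_distance(g, p, p) == 0.0

    def test_open_water_reduces_to_straight_line(self, open_sea_grid):
        g = open_sea_grid
        a = (float(g.lon_centers[0]), float(g.lat_centers[20]))
        b = (float(g.lon_centers[50]), float(g.lat_centers[20]))  # 100 km east
        d = sea_distance(g, a, b)
        assert abs(d - 100.0) <= g.cell_km

    def test_wall_with_gap_matches_dijkstra_oracle(self):
        sea = np.ones((9, 9), dtype=bool)
        sea[:8, 4] = False  # land wall with a gap at the top row
        g = km_grid(np.arange(9) * 5.0, np.arange(9) * 5.0, sea=sea)
        sd = SeaDistance(g)
        a = (float(g.lon_centers[0]), float(g.lat_centers[0]))
        b = (float(g.lon_centers[8]), float(g.lat_centers[0]))
        got = sd.distance(a, b)
        # oracle uses the grid's own metric cell sizes (cos-lat corrected)
        want = _dijkstra_oracle(sea, g.dx_km, g.dy_km, (0, 0), (0, 8))
        np.testing.assert_allclose(got, want, rtol=1e-12)
        assert got > 40.0  # forced detour, longer than the straight line

    def test_land_endpoint_errors_and_disconnected_is_inf(self):
        sea = np.ones((5, 5), dtype=bool)
        sea[:, 2] = False  # full wall splits the sea in two
        g = km_grid(np.arange(5) * 5.0, np.arange(5) * 5.0, sea=sea)
        sd = SeaDistance(g)
        left = (float(g.lon_centers[0]), float(g.lat_centers[2]))
        right = (float(g.lon_centers[4]), float(g.lat_centers[2]))
        wall = (float(g.lon_centers[2]), float(g.lat_centers[2]))
        assert np.isinf(sd.distance(left, right))
        with pytest.raises(ValueError, match="land"):
            sd.distance(left, wall)

    def test_metric_properties_on_random_pairs(self, small_basin):
        spec, grid, coast, sectors = small_basin
        sd = SeaDistance(grid)
        rng = np.random.default_rng(11)
        yy, xx = np.where(grid.sea_mask)
        pick = rng.choice(yy.size, size=5, replace=False)
        pts = [(float(grid.lon_centers[xx[i]]), float(grid.lat_centers[yy[i]])) for i in pick]
        for i in range(5):
            for j in range(5):
                dij = sd.distance(pts[i], pts[j])
                # symmetry
                np.testing.assert_allclose(dij, sd.distance(pts[j], pts[i]), rtol=1e-12)
                # lower-bounded by the straight line (within fp noise)
                xi, yi = grid.proj.to_km(*pts[i])
                xj, yj = grid.proj.to_km(*pts[j])
                assert dij >= np.hypot(xi - xj, yi - yj) - 1e-9
                # triangle inequality through any third point
                for k in range(5):
                    assert dij <= sd.distance(pts[i], pts[k]) + sd.distance(pts[k], pts[j]) + 1e-9
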