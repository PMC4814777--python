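"""Coastal geometry: grids, coastline sectorization and within-sea distances.

The connectivity analysis discretizes a coastline into consecutive segments of
fixed length (sectors, by default 25 km), groups them into regions, and assigns
each near-coast grid cell to the sector whose segment lies nearest.  Dispersal
distances between points are measured as shortest paths constrained to sea
cells ("net displacement" in the movement-ecology sense), computed with
Dijkstra's algorithm on the 8-connected grid lattice.

Coordinates are (lon, lat) in degrees.  Distances use a local equirectangular
projection about a reference latitude, which is adequate at basin scale and
keeps a regular lon/lat grid metrically uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "LocalProjection",
    "Grid",
    "Sector",
    "SectorSet",
    "HabitatMask",
    "build_sectors",
    "assign_cells_to_sectors",
    "build_habitat_mask",
    "SeaDistance",
    "sea_distance",
]


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular projection about (``lon0``, ``lat0``), in km."""

    lon0: float
    lat0: float

    @property
    def km_per_deg_lat(self) -> float:
        return EARTH_RADIUS_KM * np.pi / 180.0

    @property
    def km_per_deg_lon(self) -> float:
        return self.km_per_deg_lat * np.cos(np.deg2rad(self.lat0))

    def to_km(self, lon, lat):
        x = (np.asarray(lon, dtype=float) - self.lon0) * self.km_per_deg_lon
        y = (np.asarray(lat, dtype=float) - self.lat0) * self.km_per_deg_lat
        return x, y

    def to_lonlat(self, x, y):
        lon = self.lon0 + np.asarray(x, dtype=float) / self.km_per_deg_lon
        lat = self.lat0 + np.asarray(y, dtype=float) / self.km_per_deg_lat
        return lon, lat


@dataclass
class Grid:
    """Regular lon/lat grid with a sea/land mask.

    Parameters
    ----------
    lon_centers, lat_centers
        Strictly monotone cell-center coordinates in degrees.
    sea_mask
        Boolean array of shape ``(n_lat, n_lon)``; True marks sea cells.
    """

    lon_centers: np.ndarray
    lat_centers: np.ndarray
    sea_mask: np.ndarray

    def __post_init__(self) -> None:
        self.lon_centers = np.asarray(self.lon_centers, dtype=float)
        self.lat_centers = np.asarray(self.lat_centers, dtype=float)
        self.sea_mask = np.asarray(self.sea_mask, dtype=bool)
        if self.sea_mask.shape != (self.n_lat, self.n_lon):
            raise ValueError(
                f"sea_mask shape {self.sea_mask.shape} does not match "
                f"(n_lat={self.n_lat}, n_lon={self.n_lon})"
            )
        for name, c in (("lon_centers", self.lon_centers), ("lat_centers", self.lat_centers)):
            d = np.diff(c)
            if c.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} must be strictly monotone")
        if np.any(np.diff(self.lon_centers) < 0) or np.any(np.diff(self.lat_centers) < 0):
            raise ValueError("descending coordinate axes are not supported; sort the grid first")
        if not self.sea_mask.any():
            raise ValueError("grid has no sea cells")
        self.proj = LocalProjection(
            float(np.mean(self.lon_centers)), float(np.mean(self.lat_centers))
        )
        self.x_km = (self.lon_centers - self.proj.lon0) * self.proj.km_per_deg_lon
        self.y_km = (self.lat_centers - self.proj.lat0) * self.proj.km_per_deg_lat

    @property
    def n_lon(self) -> int:
        return self.lon_centers.size

    @property
    def n_lat(self) -> int:
        return self.lat_centers.size

    @property
    def dx_km(self) -> float:
        return float(np.mean(np.diff(self.x_km))) if self.n_lon > 1 else 1.0

    @property
    def dy_km(self) -> float:
        return float(np.mean(np.diff(self.y_km))) if self.n_lat > 1 else 1.0

    @property
    def cell_km(self) -> float:
        """Approximate cell side in km."""
        return float(np.sqrt(self.dx_km * self.dy_km))

    @property
    def cell_area_km2(self) -> float:
        return float(self.dx_km * self.dy_km)

    @staticmethod
    def _nearest(centers: np.ndarray, vals: np.ndarray) -> np.ndarray:
        if centers.size == 1:
            return np.zeros(np.shape(vals), dtype=int)
        j = np.clip(np.searchsorted(centers, vals), 1, centers.size - 1)
        use_left = (vals - centers[j - 1]) <= (centers[j] - vals)
        return np.where(use_left, j - 1, j)

    def cell_index(self, lon, lat):
        """Indices ``(iy, ix)`` of the cell whose center is nearest each point."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return self._nearest(self.lat_centers, lat), self._nearest(self.lon_centers, lon)

    def is_sea(self, lon, lat):
        iy, ix = self.cell_index(lon, lat)
        return self.sea_mask[iy, ix]

    def in_bounds(self, lon, lat):
        """True where the point lies within the grid extent (cells incl. halves)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        hx = 0.5 * abs(self.lon_centers[1] - self.lon_centers[0]) if self.n_lon > 1 else 0.5
        hy = 0.5 * abs(self.lat_centers[1] - self.lat_centers[0]) if self.n_lat > 1 else 0.5
        return (
            (lon >= self.lon_centers[0] - hx)
            & (lon <= self.lon_centers[-1] + hx)
            & (lat >= self.lat_centers[0] - hy)
            & (lat <= self.lat_centers[-1] + hy)
        )


# ---------------------------------------------------------------------------
# Coastline sectorization
# ---------------------------------------------------------------------------


@dataclass
class Sector:
    """A coastline segment of ~``segment_length`` km; the node unit of
    connectivity matrices."""

    id: int              # 1-based, contiguous along the coastline
    region_id: int       # 1-based
    vertices: np.ndarray  # (k, 2) lon/lat polyline of the segment
    length_km: float
    start_km: float      # arc-length position of the segment start
    end_km: float
    midpoint: tuple      # (lon, lat) at mid arc-length


@dataclass
class SectorSet:
    """All sectors of a coastline plus (optionally) their grid footprints."""

    sectors: list
    coastline: np.ndarray          # (M, 2) lon/lat
    closed: bool                   # first vertex == last vertex
    proj: LocalProjection
    total_length_km: float
    footprints: np.ndarray | None = field(default=None)  # (n_lat, n_lon) int; 0 = unassigned

    def __len__(self) -> int:
        return len(self.sectors)

    @property
    def n(self) -> int:
        return len(self.sectors)

    @property
    def ids(self) -> np.ndarray:
        return np.array([s.id for s in self.sectors], dtype=int)

    @property
    def region_ids(self) -> np.ndarray:
        return np.array([s.region_id for s in self.sectors], dtype=int)

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([s.midpoint for s in self.sectors], dtype=float)

    def signed_offset(self, i, j):
        """Directed displacement in sectors, ``j - i``.

        On a closed coastline the offset is wrapped to the nearest signed
        value in ``(-N/2, N/2]`` so that movement across the numbering origin
        is counted by the short way round.
        """
        off = np.asarray(j, dtype=int) - np.asarray(i, dtype=int)
        if self.closed:
            n = self.n
            off = (off + n // 2 - 1) % n - (n // 2 - 1)
        return off

    def to_frame(self, areas: dict | None = None):
        """Sector table: id, region, midpoint, length (+ per-species area)."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "sector_id": self.ids,
                "region_id": self.region_ids,
                "lon": self.midpoints[:, 0],
                "lat": self.midpoints[:, 1],
                "length_km": [s.length_km for s in self.sectors],
            }
        )
        if areas:
            for name, a in areas.items():
                df[f"area_km2_{name}"] = np.asarray(a, dtype=float)
        return df


def _polyline_km(coastline: np.ndarray, proj: LocalProjection) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(coastline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("coastline must be an (M, 2) array of lon/lat with M >= 2")
    x, y = proj.to_km(pts[:, 0], pts[:, 1])
    xy = np.column_stack([x, y])
    seg = np.hypot(*np.diff(xy, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return xy, s


def _point_at(xy: np.ndarray, s: np.ndarray, at: float) -> np.ndarray:
    """Point on the polyline at arc-length ``at``."""
    at = min(max(at, 0.0), s[-1])
    k = int(np.searchsorted(s, at, side="right") - 1)
    k = min(k, len(s) - 2)
    ds = s[k + 1] - s[k]
    t = 0.0 if ds == 0 else (at - s[k]) / ds
    return xy[k] + t * (xy[k + 1] - xy[k])


def build_sectors(
    coastline: np.ndarray,
    segment_length_km: float = 25.0,
    region_breaks: Sequence[float] | None = None,
    proj: LocalProjection | None = None,
    min_remainder_km: float = 1e-6,
) -> SectorSet:
    """Approximate a coastline with a chain of fixed-length segments.

    Parameters
    ----------
    coastline
        (M, 2) lon/lat polyline.  A closed perimeter (first == last vertex)
        is detected automatically.
    segment_length_km
        Target segment length (default 25 km).
    region_breaks
        Arc-length positions (km along the chain) at which region membership
        increments; sectors before the first break belong to region 1.
    proj
        Projection to use; defaults to one centered on the coastline.

    Returns
    -------
    SectorSet
        Sectors numbered 1..N sequentially along the chain.  A terminal
        remainder shorter than ``segment_length_km`` becomes its own shorter
        sector, so the chain always covers the whole coastline.
    """
    pts = np.asarray(coastline, dtype=float)
    if proj is None:
        proj = LocalProjection(float(np.mean(pts[:, 0])), float(np.mean(pts[:, 1])))
    xy, s = _polyline_km(pts, proj)
    total = float(s[-1])
    if total <= 0:
        raise ValueError("degenerate (zero-length) coastline")
    if segment_length_km <= 0:
        raise ValueError("segment_length_km must be positive")
    if total < segment_length_km - min_remainder_km:
        raise ValueError(
            f"coastline length {total:.3f} km is shorter than one segment "
            f"({segment_length_km} km)"
        )

    n_full = int(np.floor(total / segment_length_km + 1e-9))
    cuts = [i * segment_length_km for i in range(n_full + 1)]
    remainder = total - n_full * segment_length_km
    if remainder > min_remainder_km:
        cuts.append(total)  # short terminal sector
    else:
        cuts[-1] = total

    closed = bool(np.allclose(pts[0], pts[-1]))
    breaks = np.sort(np.asarray(region_breaks, dtype=float)) if region_breaks is not None else np.array([])
    if breaks.size and (breaks.min() < 0 or breaks.max() > total + 1e-6):
        raise ValueError("region_breaks must lie on the coastline (0 <= break <= length)")

    sectors: list[Sector] = []
    for i in range(len(cuts) - 1):
        a, b = cuts[i], cuts[i + 1]
        inner = xy[(s > a + 1e-9) & (s < b - 1e-9)]
        verts_km = np.vstack([_point_at(xy, s, a), inner, _point_at(xy, s, b)])
        lon, lat = proj.to_lonlat(verts_km[:, 0], verts_km[:, 1])
        mid_km = _point_at(xy, s, 0.5 * (a + b))
        mlon, mlat = proj.to_lonlat(mid_km[0], mid_km[1])
        region = 1 + int(np.searchsorted(breaks, 0.5 * (a + b), side="right")) if breaks.size else 1
        sectors.append(
            Sector(
                id=i + 1,
                region_id=region,
                vertices=np.column_stack([lon, lat]),
                length_km=b - a,
                start_km=a,
                end_km=b,
                midpoint=(float(mlon), float(mlat)),
            )
        )
    return SectorSet(sectors=sectors, coastline=pts, closed=closed, proj=proj, total_length_km=total)


def _min_dist_to_polyline(px: np.ndarray, py: np.ndarray, verts_xy: np.ndarray) -> np.ndarray:
    """Min distance from points (px, py) to a polyline, vectorized over points."""
    best = np.full(px.shape, np.inf)
    for k in range(len(verts_xy) - 1):
        p = verts_xy[k]
        q = verts_xy[k + 1]
        d = q - p
        L2 = d @ d
        if L2 == 0:
            dist = np.hypot(px - p[0], py - p[1])
        else:
            t = np.clip(((px - p[0]) * d[0] + (py - p[1]) * d[1]) / L2, 0.0, 1.0)
            dist = np.hypot(px - (p[0] + t * d[0]), py - (p[1] + t * d[1]))
        np.minimum(best, dist, out=best)
    return best


def assign_cells_to_sectors(
    grid: Grid,
    sectors: SectorSet,
    max_coastal_distance_km: float = 30.0,
) -> np.ndarray:
    """Assign each sea cell within the coastal band to its nearest sector.

    Each sea cell whose center lies within ``max_coastal_distance_km`` of the
    coastline is labelled with the id of the sector owning the nearest
    segment; exact ties go to the lower sector id.  Cells beyond the band (or
    on land) get label 0.  The labels are also stored on
    ``sectors.footprints``.
    """
    X, Y = np.meshgrid(grid.x_km, grid.y_km)
    # sector polylines were built in (possibly) another projection reference;
    # reproject through lon/lat into the grid's frame
    best = np.full(X.shape, np.inf)
    label = np.zeros(X.shape, dtype=int)
    for sec in sectors.sectors:
        vx, vy = grid.proj.to_km(sec.vertices[:, 0], sec.vertices[:, 1])
        d = _min_dist_to_polyline(X, Y, np.column_stack([vx, vy]))
        better = d < best - 1e-9  # ties keep the earlier (lower) id
        label[better] = sec.id
        best[better] = d[better]
    label[~grid.sea_mask] = 0
    label[best > max_coastal_distance_km] = 0
    sectors.footprints = label
    return label


@dataclass
class HabitatMask:
    """Per-species suitable cells and the suitable area of each sector.

    ``sector_area_km2[k-1]`` is the suitable area (km^2) inside sector ``k``'s
    footprint; a sector with zero suitable area is unsuitable for the species.
    """

    species: str
    suitable: np.ndarray                 # (n_lat, n_lon) bool
    sector_area_km2: np.ndarray | None = None  # (N,) aligned with sector ids 1..N

    @property
    def suitable_sectors(self) -> np.ndarray:
        """Boolean (N,) mask of sectors with positive suitable area."""
        if self.sector_area_km2 is None:
            raise ValueError("sector areas not computed (no footprints given)")
        return self.sector_area_km2 > 0


def build_habitat_mask(
    species: str,
    species_range: np.ndarray,
    depth_m: np.ndarray,
    depth_range: tuple[float, float],
    grid: Grid,
    sectors: SectorSet | None = None,
) -> HabitatMask:
    """Suitable habitat = species range ∩ depth band ∩ sea.

    ``depth_m`` is positive downwards.  When ``sectors`` carries footprints,
    per-sector suitable areas are summed from the cell area.
    """
    lo, hi = depth_range
    if lo > hi:
        raise ValueError(f"inverted depth range ({lo}, {hi})")
    species_range = np.asarray(species_range, dtype=bool)
    depth_m = np.asarray(depth_m, dtype=float)
    if species_range.shape != grid.sea_mask.shape or depth_m.shape != grid.sea_mask.shape:
        raise ValueError("species_range and depth grids must be congruent with the grid")
    suitable = species_range & (depth_m >= lo) & (depth_m <= hi) & grid.sea_mask
    areas = None
    if sectors is not None:
        if sectors.footprints is None:
            raise ValueError("sector footprints not built; call assign_cells_to_sectors first")
        lab = sectors.footprints
        counts = np.bincount(lab[suitable & (lab > 0)], minlength=sectors.n + 1)[1:]
        areas = counts.astype(float) * grid.cell_area_km2
    return HabitatMask(species=species, suitable=suitable, sector_area_km2=areas)


# ---------------------------------------------------------------------------
# Within-sea shortest distances
# ---------------------------------------------------------------------------


class SeaDistance:
    """Shortest within-sea distances on the 8-connected cell lattice.

    Horizontal/vertical steps cost the center-to-center distance; diagonal
    steps cost the hypotenuse.  The result is within one cell size of the
    straight-line distance in open water and routes around land otherwise.
    """

    def __init__(self, grid: Grid):
        self.grid = grid
        n = grid.n_lat * grid.n_lon
        sea = grid.sea_mask
        dx, dy = abs(grid.dx_km), abs(grid.dy_km)
        rows, cols, wts = [], [], []
        idx = np.arange(n).reshape(grid.n_lat, grid.n_lon)
        steps = [
            (0, 1, dx), (1, 0, dy), (1, 1, np.hypot(dx, dy)), (1, -1, np.hypot(dx, dy)),
        ]
        for di, dj, w in steps:
            src_r = slice(max(0, -di), grid.n_lat - max(0, di))
            dst_r = slice(max(0, di), grid.n_lat - max(0, -di))
            src_c = slice(max(0, -dj), grid.n_lon - max(0, dj))
            dst_c = slice(max(0, dj), grid.n_lon - max(0, -dj))
            ok = sea[src_r, src_c] & sea[dst_r, dst_c]
            rows.append(idx[src_r, src_c][ok])
            cols.append(idx[dst_r, dst_c][ok])
            wts.append(np.full(ok.sum(), w))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        wts = np.concatenate(wts)
        # symmetric graph
        self._graph = coo_matrix(
            (np.concatenate([wts, wts]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
            shape=(n, n),
        ).tocsr()

    def _node(self, lon, lat, snap_to_sea: bool = False) -> np.ndarray:
        iy, ix = self.grid.cell_index(lon, lat)
        iy, ix = np.atleast_1d(iy), np.atleast_1d(ix)
        on_land = ~self.grid.sea_mask[iy, ix]
        if on_land.any():
            if not snap_to_sea:
                raise ValueError("position falls on a land cell")
            if not hasattr(self, "_sea_tree"):
                from scipy.spatial import cKDTree

                yy, xx = np.where(self.grid.sea_mask)
                self._sea_cells = yy * self.grid.n_lon + xx
                self._sea_tree = cKDTree(
                    np.column_stack([self.grid.x_km[xx], self.grid.y_km[yy]])
                )
            x, y = self.grid.proj.to_km(np.atleast_1d(lon)[on_land], np.atleast_1d(lat)[on_land])
            _, j = self._sea_tree.query(np.column_stack([x, y]))
            nodes = iy * self.grid.n_lon + ix
            nodes[on_land] = self._sea_cells[j]
            return nodes
        return iy * self.grid.n_lon + ix

    def from_nodes(self, nodes: np.ndarray) -> np.ndarray:
        """Distance matrix (len(nodes), n_cells) from the given flat cell nodes."""
        return _csgraph_dijkstra(self._graph, directed=False, indices=np.atleast_1d(nodes))

    def distance(self, a: tuple[float, float], b: tuple[float, float]) -> float:
        """Shortest within-sea distance (km) between two (lon, lat) positions.

        Returns ``inf`` when no sea path exists.
        """
        na = self._node(a[0], a[1])[0]
        nb = self._node(b[0], b[1])[0]
        d = _csgraph_dijkstra(self._graph, directed=False, indices=na)
        return float(d[nb])

    def pairwise(self, lons: np.ndarray, lats: np.ndarray,
                 lone: np.ndarray, late: np.ndarray) -> np.ndarray:
        """Per-pair distances start_i -> end_i, batched over unique start cells."""
        ns = self._node(lons, lats)
        ne = self._node(lone, late)
        uniq, inv = np.unique(ns, return_inverse=True)
        D = self.from_nodes(uniq)
        return D[inv, ne]

    def pairwise_matrix(self, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
        """All-pairs distance matrix between the given points.

        Points falling on a land cell (e.g. sector midpoints sitting exactly
        on the coastline) are snapped to the nearest sea cell.
        """
        nodes = self._node(lons, lats, snap_to_sea=True)
        uniq, inv = np.unique(nodes, return_inverse=True)
        D = self.from_nodes(uniq)
        return D[inv][:, nodes]


def sea_distance(grid: Grid, a: tuple[float, float], b: tuple[float, float]) -> float:
    """One-shot within-sea shortest distance; see :class:`SeaDistance`."""
    return SeaDistance(grid).distance(a, b)
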