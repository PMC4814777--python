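"""Propagule release, passive advection and fate classification.

Propagules (seagrass fruits, fish larvae — any passively dispersing stage)
are released uniformly over the suitable habitat of their species during the
species-specific reproduction season, advected by the daily velocity fields
for the duration of the dispersing stage, and classified at the end of that
phase: a propagule is successful if it ends in a suitable cell belonging to a
coastal sector; it fails if it ends in unsuitable water or leaves the model
domain.

Integration is 4th-order Runge-Kutta with bilinear spatial interpolation of
the velocity field and piecewise-constant (daily) time dependence.  There is
no active behaviour, mortality or growth; an optional random-walk horizontal
diffusivity is available for sensitivity runs and is off by default.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86400.0
M_PER_S_TO_KM_PER_DAY = SECONDS_PER_DAY / 1000.0

OUTCOME_SETTLED = "settled"
OUTCOME_UNSUITABLE = "failed_unsuitable"
OUTCOME_EXITED = "failed_exited"

__all__ = [
    "SpeciesTraits",
    "ReleaseSet",
    "EndStates",
    "release_schedule",
    "advect",
    "classify_fates",
    "simulate_species_year",
]


@dataclass
class SpeciesTraits:
    """Dispersal-relevant life-history traits of one species.

    Parameters
    ----------
    release_window
        (start, end) day-of-year of propagule release, inclusive.
    dispersal_days
        Mean duration of the dispersing stage; ``dispersal_sd`` optionally
        gives its standard deviation for per-propagule durations.
    dispersal_depth_m
        Depth at which propagules drift (selects the velocity layer; the
        transport model itself is horizontal).
    recruitment_depth_range
        (min, max) bottom depth in m within which the species can recruit.
    """

    name: str
    release_window: tuple[int, int]
    dispersal_days: float
    dispersal_sd: float | None = None
    dispersal_depth_m: float = 0.0
    recruitment_depth_range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        s, e = self.release_window
        if not (1 <= s <= e <= 366):
            raise ValueError(f"release window must satisfy 1 <= start <= end <= 366, got {self.release_window}")
        if self.dispersal_days <= 0:
            raise ValueError("dispersal_days must be positive")
        lo, hi = self.recruitment_depth_range
        if lo > hi:
            raise ValueError("inverted recruitment depth range")


@dataclass
class ReleaseSet:
    """Initial conditions of one species-year batch of propagules."""

    lon: np.ndarray
    lat: np.ndarray
    date: np.ndarray          # datetime64[D] release dates
    source_sector: np.ndarray  # int, 1-based sector ids
    year: int
    species: str

    @property
    def n(self) -> int:
        return self.lon.size

    def __len__(self) -> int:
        return self.n


@dataclass
class EndStates:
    """Positions at the end of the dispersing phase, plus exit flags."""

    lon: np.ndarray
    lat: np.ndarray
    exited: np.ndarray        # bool: crossed the open boundary (frozen there)
    trajectories: np.ndarray | None = None  # (n_steps+1, n, 2) lon/lat if recorded


def _doy_to_date(year: int, doy) -> np.ndarray:
    return np.datetime64(f"{year}-01-01", "D") + (np.asarray(doy, dtype=int) - 1)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (exact sum)."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        return np.zeros(w.size, dtype=int)
    quota = total * w / w.sum()
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")  # ties -> lower index
        base[order[:short]] += 1
    return base


def release_schedule(
    traits: SpeciesTraits,
    habitat,
    sectors,
    grid,
    year: int,
    n_total: int | None = None,
    n_per_cell_per_day: int | None = None,
    release_every_days: int = 1,
    placement: str = "uniform",
    seed: int | np.random.Generator = 0,
) -> ReleaseSet:
    """Uniform releases over suitable habitat during the release season.

    Releases are spread evenly over the release days (every
    ``release_every_days``-th day of the window) and uniformly across the
    suitable cells that belong to a sector footprint, so per-sector release
    counts are proportional to suitable area.  ``placement`` is "uniform"
    (random position within the cell) or "center".  Exactly one of
    ``n_total`` / ``n_per_cell_per_day`` must be given.
    """
    if (n_total is None) == (n_per_cell_per_day is None):
        raise ValueError("give exactly one of n_total or n_per_cell_per_day")
    if placement not in ("uniform", "center"):
        raise ValueError("placement must be 'uniform' or 'center'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lab = sectors.footprints
    if lab is None:
        raise ValueError("sector footprints not built")
    cells = np.argwhere(habitat.suitable & (lab > 0))
    s, e = traits.release_window
    days = np.arange(s, e + 1, release_every_days)
    if cells.size == 0:
        warnings.warn(f"species {traits.name}: no suitable habitat in year {year}; empty release set")
        empty = np.array([], dtype=float)
        return ReleaseSet(empty, empty, np.array([], dtype="datetime64[D]"),
                          np.array([], dtype=int), year, traits.name)

    n_cells = cells.shape[0]
    n_days = days.size
    if n_per_cell_per_day is not None:
        counts = np.full(n_cells * n_days, int(n_per_cell_per_day))
    else:
        counts = _largest_remainder(np.ones(n_cells * n_days), int(n_total))
    # (cell, day) pairs laid out cell-major so area proportionality is exact per day
    pair_cell = np.repeat(np.arange(n_cells), n_days)
    pair_day = np.tile(np.arange(n_days), n_cells)
    rep = np.repeat(np.arange(n_cells * n_days), counts)
    ci = pair_cell[rep]
    di = pair_day[rep]

    iy = cells[ci, 0]
    ix = cells[ci, 1]
    lon = grid.lon_centers[ix].astype(float).copy()
    lat = grid.lat_centers[iy].astype(float).copy()
    if placement == "uniform":
        dlon = abs(grid.lon_centers[1] - grid.lon_centers[0]) if grid.n_lon > 1 else 1.0
        dlat = abs(grid.lat_centers[1] - grid.lat_centers[0]) if grid.n_lat > 1 else 1.0
        lon += (rng.random(lon.size) - 0.5) * dlon
        lat += (rng.random(lat.size) - 0.5) * dlat
    dates = _doy_to_date(year, days[di])
    src = lab[iy, ix]
    return ReleaseSet(lon=lon, lat=lat, date=dates, source_sector=src,
                      year=year, species=traits.name)


class _Interp:
    """Bilinear interpolation of one day's u, v at particle positions (km)."""

    def __init__(self, grid):
        self.x = grid.x_km
        self.y = grid.y_km
        self.nx = grid.n_lon
        self.ny = grid.n_lat

    def set_day(self, u: np.ndarray, v: np.ndarray) -> None:
        self.u = u
        self.v = v

    def __call__(self, px: np.ndarray, py: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x, y = self.x, self.y
        ix = np.clip(np.searchsorted(x, px) - 1, 0, self.nx - 2)
        iy = np.clip(np.searchsorted(y, py) - 1, 0, self.ny - 2)
        tx = np.clip((px - x[ix]) / (x[ix + 1] - x[ix]), 0.0, 1.0)
        ty = np.clip((py - y[iy]) / (y[iy + 1] - y[iy]), 0.0, 1.0)
        w00 = (1 - tx) * (1 - ty)
        w01 = tx * (1 - ty)
        w10 = (1 - tx) * ty
        w11 = tx * ty
        u = (w00 * self.u[iy, ix] + w01 * self.u[iy, ix + 1]
             + w10 * self.u[iy + 1, ix] + w11 * self.u[iy + 1, ix + 1])
        v = (w00 * self.v[iy, ix] + w01 * self.v[iy, ix + 1]
             + w10 * self.v[iy + 1, ix] + w11 * self.v[iy + 1, ix + 1])
        return u, v


def advect(
    release: ReleaseSet,
    field,
    duration_days: float | np.ndarray,
    dt_hours: float = 1.0,
    boundary_policy: str = "slide",
    diffusivity_m2_s: float = 0.0,
    seed: int | np.random.Generator = 0,
    record_trajectories: bool = False,
) -> EndStates:
    """Track propagules through the daily velocity fields.

    4th-order Runge-Kutta on dX/dt = u(X, t) with bilinear spatial
    interpolation; the daily-mean fields are held piecewise-constant in time.
    Land velocities count as zero in the interpolation; a step that would put
    a propagule onto a land cell is handled per ``boundary_policy``:
    "slide" tries the along-coast component of the step (x-only, then
    y-only), "freeze" cancels the step.  A propagule crossing the open grid
    boundary is frozen where it left and flagged ``exited``.

    ``duration_days`` is a scalar or a per-propagule array; propagules start
    at 00:00 of their release date and stop after their own duration.
    """
    if dt_hours <= 0:
        raise ValueError("dt_hours must be positive")
    if boundary_policy not in ("slide", "freeze"):
        raise ValueError("boundary_policy must be 'slide' or 'freeze'")
    grid = field.grid
    n = release.n
    dur = np.broadcast_to(np.asarray(duration_days, dtype=float), (n,)).copy()
    if np.any(dur <= 0):
        raise ValueError("durations must be positive")
    if n == 0:
        return EndStates(np.array([]), np.array([]), np.array([], dtype=bool))

    t0 = release.date.min()
    start_day = (release.date - t0).astype(int)          # days after t0
    end_time = start_day + dur                           # days after t0
    horizon = float(end_time.max())
    field_start = (t0 - field.times[0]).astype(int)
    if field_start < 0 or field_start + int(np.ceil(horizon)) > field.n_time:
        raise ValueError("velocity field does not cover the release dates plus duration")

    px, py = grid.proj.to_km(release.lon, release.lat)
    px = px.astype(float).copy()
    py = py.astype(float).copy()
    exited = np.zeros(n, dtype=bool)
    xmin, xmax = grid.x_km[0] - grid.dx_km / 2, grid.x_km[-1] + grid.dx_km / 2
    ymin, ymax = grid.y_km[0] - grid.dy_km / 2, grid.y_km[-1] + grid.dy_km / 2

    n_days_needed = int(np.ceil(horizon - 1e-9))
    day_slice = slice(field_start, field_start + n_days_needed)
    u_filled = np.nan_to_num(field.u[day_slice], nan=0.0) * M_PER_S_TO_KM_PER_DAY
    v_filled = np.nan_to_num(field.v[day_slice], nan=0.0) * M_PER_S_TO_KM_PER_DAY
    interp = _Interp(grid)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    dt = dt_hours / 24.0
    n_days_sim = n_days_needed
    steps_per_day = int(np.ceil(24.0 / dt_hours - 1e-9))
    traj = [np.column_stack([release.lon, release.lat])] if record_trajectories else None

    for day in range(n_days_sim):
        interp.set_day(u_filled[day], v_filled[day])
        for k in range(steps_per_day):
            t_now = day + k * dt
            # per-particle step length: clipped to remaining lifetime and to
            # the end of the current field day
            h = np.clip(np.minimum(end_time - t_now, (day + 1) - t_now), 0.0, dt)
            active = (start_day <= t_now) & (h > 0) & ~exited
            if not active.any():
                continue
            h_a = h[active]
            xa = px[active]
            ya = py[active]

            def rhs(x, y):
                return interp(np.clip(x, xmin, xmax), np.clip(y, ymin, ymax))

            k1x, k1y = rhs(xa, ya)
            k2x, k2y = rhs(xa + 0.5 * h_a * k1x, ya + 0.5 * h_a * k1y)
            k3x, k3y = rhs(xa + 0.5 * h_a * k2x, ya + 0.5 * h_a * k2y)
            k4x, k4y = rhs(xa + h_a * k3x, ya + h_a * k3y)
            nx = xa + h_a / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
            ny = ya + h_a / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
            if diffusivity_m2_s > 0:
                # K in m^2/s -> km^2/day
                K = diffusivity_m2_s * SECONDS_PER_DAY / 1e6
                sig = np.sqrt(2.0 * K * h_a)
                nx = nx + sig * rng.standard_normal(nx.size)
                ny = ny + sig * rng.standard_normal(ny.size)

            out = (nx < xmin) | (nx > xmax) | (ny < ymin) | (ny > ymax)
            nx_c = np.clip(nx, xmin, xmax)
            ny_c = np.clip(ny, ymin, ymax)

            lon_n, lat_n = grid.proj.to_lonlat(nx_c, ny_c)
            on_land = ~grid.is_sea(lon_n, lat_n)
            if on_land.any():
                if boundary_policy == "slide":
                    # keep only the x-component of the step, else only y, else stay
                    tx, tyy = nx_c.copy(), ya.copy()
                    lon_t, lat_t = grid.proj.to_lonlat(tx, tyy)
                    ok_x = grid.is_sea(lon_t, lat_t)
                    ty2x, ty2y = xa.copy(), ny_c.copy()
                    lon_t2, lat_t2 = grid.proj.to_lonlat(ty2x, ty2y)
                    ok_y = grid.is_sea(lon_t2, lat_t2)
                    nx_c = np.where(on_land, np.where(ok_x, tx, np.where(ok_y, xa, xa)), nx_c)
                    ny_c = np.where(on_land, np.where(ok_x, ya, np.where(ok_y, ny_c, ya)), ny_c)
                else:  # freeze
                    nx_c = np.where(on_land, xa, nx_c)
                    ny_c = np.where(on_land, ya, ny_c)

            px[active] = nx_c
            py[active] = ny_c
            newly_exited = np.zeros(n, dtype=bool)
            newly_exited[active] = out
            exited |= newly_exited
        if record_trajectories:
            lon_d, lat_d = grid.proj.to_lonlat(px, py)
            traj.append(np.column_stack([lon_d, lat_d]))

    lon_e, lat_e = grid.proj.to_lonlat(px, py)
    return EndStates(
        lon=lon_e, lat=lat_e, exited=exited,
        trajectories=np.array(traj) if record_trajectories else None,
    )


def classify_fates(release: ReleaseSet, end: EndStates, habitat, sectors, grid) -> pd.DataFrame:
    """Classify each propagule's fate at the end of its dispersing phase.

    A propagule that crossed the open boundary failed (``failed_exited``);
    one ending in a suitable cell assigned to a sector settled there
    (``settled``, with that sink sector); any other end point is
    ``failed_unsuitable``.  Returns a tidy fate table.
    """
    n = release.n
    outcome = np.full(n, OUTCOME_UNSUITABLE, dtype=object)
    sink = np.zeros(n, dtype=int)
    if n:
        iy, ix = grid.cell_index(end.lon, end.lat)
        lab = sectors.footprints
        ok = habitat.suitable[iy, ix] & (lab[iy, ix] > 0) & ~end.exited
        outcome[ok] = OUTCOME_SETTLED
        sink[ok] = lab[iy, ix][ok]
        outcome[end.exited] = OUTCOME_EXITED
    return pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "species": release.species,
            "year": release.year,
            "source_sector": release.source_sector,
            "outcome": outcome,
            "sink_sector": sink,
            "start_lon": release.lon,
            "start_lat": release.lat,
            "end_lon": end.lon,
            "end_lat": end.lat,
        }
    )


def simulate_species_year(
    traits: SpeciesTraits,
    habitat,
    sectors,
    grid,
    field,
    year: int,
    n_particles: int,
    seed: int = 0,
    dt_hours: float = 1.0,
    release_every_days: int = 1,
    boundary_policy: str = "slide",
    diffusivity_m2_s: float = 0.0,
    placement: str = "uniform",
) -> pd.DataFrame:
    """Release, advect and classify one species-year; returns the fate table.

    Per-propagule dispersal durations are the species mean, or truncated
    normal draws (>= 1 day) when the traits carry a standard deviation.
    """
    name_key = zlib.crc32(traits.name.encode()) % (2**31)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(name_key, year))
    r_rng, d_rng, a_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    release = release_schedule(
        traits, habitat, sectors, grid, year,
        n_total=n_particles, release_every_days=release_every_days,
        placement=placement, seed=r_rng,
    )
    if release.n == 0:
        return classify_fates(release, EndStates(np.array([]), np.array([]), np.array([], dtype=bool)),
                              habitat, sectors, grid)
    if traits.dispersal_sd:
        dur = d_rng.normal(traits.dispersal_days, traits.dispersal_sd, release.n)
        dur = np.maximum(dur, 1.0)
    else:
        dur = traits.dispersal_days
    end = advect(release, field, dur, dt_hours=dt_hours, boundary_policy=boundary_policy,
                 diffusivity_m2_s=diffusivity_m2_s, seed=a_rng)
    return classify_fates(release, end, habitat, sectors, grid)
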