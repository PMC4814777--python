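"""End-to-end orchestration: one config in, a directory of results out.

Stages run in the order simulate -> kernels -> metrics -> community, per
species, then aggregate the assemblage.  All randomness is routed through
one master seed (per-stage generators are spawned from it), so a re-run with
the same config is bit-identical.  A run manifest records the config hash,
per-file checksums, particle conservation counts and wall times.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import connectivity as conn
from . import kernels as kern
from .fields import (
    SyntheticBasinSpec,
    make_gyre_field,
    make_synthetic_community,
    read_velocity,
)
from .geometry import SeaDistance, assign_cells_to_sectors, build_habitat_mask, build_sectors
from .lagrangian import OUTCOME_SETTLED, SpeciesTraits, simulate_species_year

__all__ = ["RunConfig", "run_all", "report", "default_demo_config"]


@dataclass
class RunConfig:
    """Everything needed for a reproducible end-to-end run."""

    output_dir: str = "metaconn_out"
    seed: int = 0
    years: list = field(default_factory=lambda: [2003, 2004, 2005])
    n_particles: int = 10_000           # per species per year
    dt_hours: float = 1.0
    release_every_days: int = 5
    boundary_policy: str = "slide"
    diffusivity_m2_s: float = 0.0
    placement: str = "uniform"
    segment_km: float = 25.0
    coastal_band_km: float = 30.0
    n_regions: int = 8
    effectiveness_denominator: str = "source"
    hotspot_threshold_percent: float = 20.0
    kernel_bin_km: float = 25.0
    assemblage: list | None = None      # default: all species
    # synthetic-domain parameters (used unless velocity_path is given)
    basin: dict = field(default_factory=dict)
    habitat_fraction: float = 0.75
    depth_slope_m_per_km: float = 3.0
    species: list | None = None         # list of trait dicts; default assemblage
    # file-based inputs (optional)
    velocity_path: str | None = None
    u_name: str = "u"
    v_name: str = "v"
    coastline_path: str | None = None   # GeoJSON LineString
    habitat_paths: dict | None = None   # species name -> NetCDF bool grid
    depth_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def trait_list(self) -> list:
        from .fields import DEFAULT_TRAITS

        if self.species is None:
            return list(DEFAULT_TRAITS)
        out = []
        for sp in self.species:
            sp = dict(sp)
            sp["release_window"] = tuple(sp["release_window"])
            if "recruitment_depth_range" in sp:
                sp["recruitment_depth_range"] = tuple(sp["recruitment_depth_range"])
            out.append(SpeciesTraits(**sp))
        return out


def default_demo_config(output_dir: str = "metaconn_out", seed: int = 0,
                        n_particles: int = 10_000) -> RunConfig:
    """The built-in synthetic demo: a 700 x 800 km closed basin with a
    cyclonic gyre, 120 perimeter sectors in 8 regions and the default
    4-species assemblage over 3 years."""
    return RunConfig(
        output_dir=output_dir,
        seed=seed,
        n_particles=n_particles,
        basin={"gyre_speed": 0.15, "noise_sd": 0.05},
    )


def _build_domain(config: RunConfig):
    """Grid, coastline, sectors, habitats, traits and velocity field."""
    traits = config.trait_list()
    if config.velocity_path is None:
        basin_kw = dict(config.basin)
        basin_kw.setdefault("seed", config.seed)
        spec = SyntheticBasinSpec(**basin_kw)
        sc = make_synthetic_community(
            basin=spec,
            n_species=len(traits),
            traits=traits,
            seed=config.seed,
            segment_length_km=config.segment_km,
            n_regions=config.n_regions,
            coastal_band_km=config.coastal_band_km,
            habitat_fraction=config.habitat_fraction,
            depth_slope_m_per_km=config.depth_slope_m_per_km,
        )
        y0, y1 = min(config.years), max(config.years)
        start = np.datetime64(f"{y0}-01-01")
        n_days = int((np.datetime64(f"{y1 + 1}-01-01") - start).astype(int))
        fieldv = make_gyre_field(spec, n_days, start=start)
        return sc.grid, sc.coastline, sc.sectors, sc.habitats, traits, fieldv

    # file-based domain
    import xarray as xr

    fieldv = read_velocity(config.velocity_path, config.u_name, config.v_name)
    grid = fieldv.grid
    if config.coastline_path is None:
        raise ValueError("file-based runs need coastline_path (GeoJSON LineString)")
    with open(config.coastline_path) as fh:
        gj = json.load(fh)
    geom = gj["features"][0]["geometry"] if gj.get("type") == "FeatureCollection" else gj.get("geometry", gj)
    coast = np.asarray(geom["coordinates"], dtype=float)
    total_guess = None
    sectors = build_sectors(coast, config.segment_km, proj=grid.proj)
    if config.n_regions > 1:
        total_guess = sectors.total_length_km
        breaks = [total_guess * k / config.n_regions for k in range(1, config.n_regions)]
        sectors = build_sectors(coast, config.segment_km, region_breaks=breaks, proj=grid.proj)
    assign_cells_to_sectors(grid, sectors, config.coastal_band_km)
    depth = None
    if config.depth_path:
        with xr.open_dataset(config.depth_path, engine="scipy") as ds:
            depth = np.asarray(ds[list(ds.data_vars)[0]].values, dtype=float)
    habitats = {}
    for tr in traits:
        if not config.habitat_paths or tr.name not in config.habitat_paths:
            raise ValueError(f"config missing habitat source for species '{tr.name}'")
        with xr.open_dataset(config.habitat_paths[tr.name], engine="scipy") as ds:
            rng_mask = np.asarray(ds[list(ds.data_vars)[0]].values).astype(bool)
        d = depth if depth is not None else np.zeros_like(rng_mask, dtype=float)
        dr = tr.recruitment_depth_range if depth is not None else (0.0, np.inf)
        habitats[tr.name] = build_habitat_mask(tr.name, rng_mask, d, dr, grid, sectors)
    return grid, coast, sectors, habitats, traits, fieldv


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_matrix_csv(m: np.ndarray, path: Path) -> None:
    n = m.shape[0]
    pd.DataFrame(m, index=np.arange(1, n + 1), columns=np.arange(1, n + 1)).to_csv(path)


def _sectors_geojson(sectors, scores: pd.DataFrame | None = None) -> dict:
    features = []
    score_by_id = {}
    if scores is not None:
        score_by_id = scores.set_index("sector_id").to_dict("index")
    for s in sectors.sectors:
        props = {"sector_id": s.id, "region_id": s.region_id, "length_km": s.length_km}
        if s.id in score_by_id:
            props.update({k: (None if pd.isna(v) else float(v) if not isinstance(v, (bool, np.bool_)) else bool(v))
                          for k, v in score_by_id[s.id].items()})
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": s.vertices.tolist()},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written).

    Stage order per species: simulate (release/advect/classify) -> dispersal
    kernels -> flow matrices and metrics -> sector indicators; then the
    community aggregation, percentile ranks, scores and hotspot list for the
    assemblage.  Particle conservation (released = settled + failed) is
    asserted between stages.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {},
        "particles": {},
        "files": {},
    }
    t_start = time.time()

    t0 = time.time()
    grid, coast, sectors, habitats, traits, fieldv = _build_domain(config)
    areas = {tr.name: habitats[tr.name].sector_area_km2 for tr in traits}
    sectors.to_frame(areas).to_csv(out / "sectors.csv", index=False)
    manifest["stages"]["domain"] = {"seconds": round(time.time() - t0, 2),
                                    "n_sectors": sectors.n}

    assemblage = config.assemblage or [tr.name for tr in traits]
    missing = [s for s in assemblage if s not in {tr.name for tr in traits}]
    if missing:
        raise ValueError(f"assemblage species without traits: {missing}")

    sea = SeaDistance(grid)
    per_species_ind = {}
    per_species_int = {}
    per_species_active = {}
    for tr in traits:
        t0 = time.time()
        fates = pd.concat(
            [
                simulate_species_year(
                    tr, habitats[tr.name], sectors, grid, fieldv, year,
                    n_particles=config.n_particles, seed=config.seed,
                    dt_hours=config.dt_hours,
                    release_every_days=config.release_every_days,
                    boundary_policy=config.boundary_policy,
                    diffusivity_m2_s=config.diffusivity_m2_s,
                    placement=config.placement,
                )
                for year in config.years
            ],
            ignore_index=True,
        )
        fates.to_csv(out / f"fates_{tr.name}.csv", index=False)
        counts = fates.groupby("outcome").size().to_dict()
        n_rel = len(fates)
        if sum(counts.values()) != n_rel:  # conservation check between stages
            raise RuntimeError(f"stage simulate[{tr.name}]: fate accounting mismatch")
        manifest["particles"][tr.name] = {"released": n_rel, **{k: int(v) for k, v in counts.items()}}
        manifest["stages"][f"simulate_{tr.name}"] = {"seconds": round(time.time() - t0, 2)}

        t0 = time.time()
        kern.net_displacement_kernel(fates, sea, sectors, bin_km=config.kernel_bin_km).to_csv(
            out / f"kernel_net_{tr.name}.csv", index=False)
        kern.directed_displacement_kernel(fates, sectors).to_csv(
            out / f"kernel_directed_{tr.name}.csv", index=False)
        kern.reachability_profile(sectors, habitats[tr.name], sea, kind="net",
                                  bin_km=config.kernel_bin_km).to_csv(
            out / f"reachability_net_{tr.name}.csv", index=False)
        manifest["stages"][f"kernels_{tr.name}"] = {"seconds": round(time.time() - t0, 2)}

        t0 = time.time()
        flow = conn.FlowMatrix.from_fates(fates, sectors.n, config.years, species=tr.name)
        n_settled = int((fates["outcome"] == OUTCOME_SETTLED).sum())
        if int(flow.counts.sum()) != n_settled:
            raise RuntimeError(f"stage metrics[{tr.name}]: settled-count mismatch")
        I = conn.intensity(flow)
        E = conn.effectiveness(I, areas[tr.name], config.effectiveness_denominator)
        P = conn.persistence(flow)
        ind = conn.sector_indicators(flow, areas[tr.name])
        per_species_ind[tr.name] = ind
        per_species_int[tr.name] = I
        per_species_active[tr.name] = conn.active_mask(flow)

        import xarray as xr

        xr.Dataset(
            {"flow": (("year", "source", "sink"), flow.counts.astype("i4"))},
            coords={"year": config.years,
                    "source": np.arange(1, sectors.n + 1),
                    "sink": np.arange(1, sectors.n + 1)},
        ).to_netcdf(out / f"flows_{tr.name}.nc", engine="scipy")
        _write_matrix_csv(I, out / f"intensity_{tr.name}.csv")
        _write_matrix_csv(E, out / f"effectiveness_{tr.name}.csv")
        _write_matrix_csv(P, out / f"persistence_{tr.name}.csv")
        conn.indicator_frame(ind, tr.name).to_csv(out / f"indicators_{tr.name}.csv", index=False)
        manifest["stages"][f"metrics_{tr.name}"] = {"seconds": round(time.time() - t0, 2)}

    t0 = time.time()
    comm_ind = comm.community_indicators({s: per_species_ind[s] for s in assemblage})
    comm_int = comm.community_matrix({s: per_species_int[s] for s in assemblage})
    scores = comm.score_table(comm_ind, config.hotspot_threshold_percent)
    hot = comm.hotspots(scores["score"].to_numpy(), config.hotspot_threshold_percent,
                        scores["sector_id"].to_numpy())
    conn.indicator_frame(comm_ind, "community").to_csv(out / "community_indicators.csv", index=False)
    _write_matrix_csv(comm_int, out / "community_intensity.csv")
    scores.to_csv(out / "scores.csv", index=False)
    hot.to_csv(out / "hotspots.csv", index=False)
    with open(out / "sectors.geojson", "w") as fh:
        json.dump(_sectors_geojson(sectors, scores), fh)
    manifest["stages"]["community"] = {"seconds": round(time.time() - t0, 2),
                                       "assemblage": assemblage,
                                       "n_hotspots": int(len(hot))}

    for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.nc")) + sorted(out.glob("*.geojson")):
        manifest["files"][p.name] = _sha256(p)
    manifest["wall_seconds"] = round(time.time() - t_start, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def _plot_matrix(ax, M: np.ndarray, areas: np.ndarray | None, title: str) -> None:
    """Heatmap in the paper-style convention: inactive potential connections
    white, rows/columns of unsuitable sectors grey."""
    import matplotlib.colors as mcolors
    from matplotlib import colormaps

    M = np.asarray(M, dtype=float)
    finite = M[np.isfinite(M) & (M > 0)]
    vmax = finite.max() if finite.size else 1.0
    img = np.ma.masked_invalid(np.where(M > 0, M, np.nan))
    cmap = colormaps["viridis"].copy()
    cmap.set_bad("white")
    ax.imshow(img, origin="lower", cmap=cmap,
              norm=mcolors.LogNorm(vmin=max(vmax * 1e-4, 1e-12), vmax=vmax),
              extent=(0.5, M.shape[1] + 0.5, 0.5, M.shape[0] + 0.5))
    if areas is not None:
        uns = np.where(np.asarray(areas) <= 0)[0]
        for k in uns:
            ax.axhspan(k + 0.5, k + 1.5, color="0.8", zorder=2)
            ax.axvspan(k + 0.5, k + 1.5, color="0.8", zorder=2)
    ax.set_xlabel("sink sector")
    ax.set_ylabel("source sector")
    ax.set_title(title)


def report(outputs_dir) -> Path:
    """Render kernel histograms, metric heatmaps, the cumulative score
    distribution and the hotspot list from a finished run directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outputs_dir)
    if not (out / "scores.csv").exists():
        raise FileNotFoundError(f"no pipeline outputs in {out}")
    sectors = pd.read_csv(out / "sectors.csv")
    scores = pd.read_csv(out / "scores.csv")
    species = sorted(p.stem.replace("intensity_", "") for p in out.glob("intensity_*.csv"))

    lines = ["# Connectivity run report", ""]
    for sp in species:
        I = pd.read_csv(out / f"intensity_{sp}.csv", index_col=0).to_numpy()
        area_col = f"area_km2_{sp}"
        areas = sectors[area_col].to_numpy() if area_col in sectors else None
        fig, ax = plt.subplots(figsize=(6, 5))
        _plot_matrix(ax, I, areas, f"intensity — {sp}")
        fig.tight_layout()
        fig.savefig(out / f"report_intensity_{sp}.png", dpi=110)
        plt.close(fig)

        kn = pd.read_csv(out / f"kernel_net_{sp}.csv")
        if len(kn):
            fig, ax = plt.subplots(figsize=(6, 4))
            for r, g in kn.groupby("region"):
                ax.step(g["bin_lo"], g["proportion"], where="post", label=f"region {r}")
            ax.set_xlabel("net displacement (km)")
            ax.set_ylabel("proportion of settled propagules")
            ax.set_title(f"net displacement kernel — {sp}")
            ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(out / f"report_kernel_{sp}.png", dpi=110)
            plt.close(fig)

    # cumulative distribution of ranks and score (0..100 on both axes)
    fig, ax = plt.subplots(figsize=(6, 4))
    for col, label in [("retention_rank", "retention"), ("source_rank", "source"),
                       ("sink_rank", "sink"), ("score", "community score")]:
        v = np.sort(scores[col].dropna().to_numpy())
        cum = 100.0 * np.arange(1, v.size + 1) / v.size
        ax.plot(np.concatenate([[0], v]), np.concatenate([[0], cum]), label=label,
                lw=2 if col == "score" else 1)
    ax.set_xlabel("percentile rank")
    ax.set_ylabel("cumulative % of sectors")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "report_score_cdf.png", dpi=110)
    plt.close(fig)

    hot = pd.read_csv(out / "hotspots.csv")
    lines.append("## Hotspots")
    if len(hot) == 0:
        lines.append("none at threshold")
    else:
        for _, row in hot.iterrows():
            lines.append(f"- sector {int(row.sector_id)}: score {row.score:.1f}")
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
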