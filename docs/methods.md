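# Methods

This note documents the model assumptions, parameter choices and numerical
conventions behind `metaconn`, and what the synthetic test system does and
does not establish about real-ocean applications.

## Transport model

Propagules are passive tracers of the horizontal flow at a fixed depth:
dX/dt = u(X, t), integrated with classical 4th-order Runge–Kutta at a default
step of 1 h. Velocities are interpolated bilinearly in space; the daily-mean
fields are held piecewise-constant in time (an optional linear time
interpolation exists in the reader for non-daily archives). Bilinear
interpolation is exact for linear fields, so solid-body-rotation orbits close
to machine-level accuracy at dt = 1 h (the test suite checks closure within
1% of the orbit radius and RK4 convergence under dt halving).

There is no larval behaviour (swimming, vertical migration, orientation),
no mortality or growth, and no density dependence — the model measures
*potential*, physically mediated connectivity. A horizontal random-walk
diffusivity (`diffusivity_m2_s`, default 0) is available for sensitivity
runs; it is seed-controlled and off by default, since the daily-mean fields
are treated as the full transport signal.

Land handling: land cells carry zero velocity inside the interpolation
stencil, which decelerates propagules approaching the coast; a step that
would land a propagule on a land cell keeps only its alongshore component
("slide", default) or is cancelled ("freeze"). A propagule crossing the open
grid boundary is frozen there and flagged; it counts as a failure at
classification, so kernels near domain edges are truncated exactly as they
would be in a regional model.

Settlement is evaluated once, at the end of the dispersing phase: success
iff the end position lies in a suitable cell assigned to a sector. There is
no competency window; dispersal duration is the species mean by default, or
per-propagule truncated-normal draws (≥ 1 day) when a standard deviation is
provided.

## Geometry conventions

Positions are (lon, lat) degrees; distances use a local equirectangular
projection about the grid center, adequate at basin scale (few hundred km)
and self-consistent across modules. Sectors are consecutive 25-km pieces of
the coastline chain; a terminal remainder shorter than the segment length
becomes its own shorter sector so the chain always covers the coast. Cells
are attributed to the sector of the nearest segment within a configurable
coastal band (default 30 km); exact ties go to the lower sector id. These
two conventions (remainder sector, nearest-segment band) are package
choices — ecological sectorizations rarely specify them — and are unit-locked
by tests.

Net displacement is the shortest within-sea path on the 8-connected cell
lattice (Dijkstra; diagonal steps cost the hypotenuse). The lattice metric
overestimates true geodesics by at most ~8% on staircase paths and is exact
along axes; at 25-km kernel bins and ~10-km cells this is adequate, and in
open water it reduces to the straight-line distance within one cell size.

## Metrics

Persistence uses the population (1/T) standard deviation and includes
zero-flux years, so occasional connections are penalized; an all-zero series
has persistence 0 and a constant nonzero series is reported as +inf — a
dedicated sentinel that is never silently capped in stored outputs (ranking
treats +inf as greater than any finite value; ties among infinities share
their count). Matrix-level effectiveness divides row i by the *source*
sector's suitable area (releases are uniform over suitable area, so area is
donating capacity); a flag switches to sink-area normalization. Sector-role
effectiveness always divides by the sector's own area, its capacity to
donate or receive.

Percentile ranks follow the "value less than or equal" reading: with M
evaluable sectors the best sector scores 100 and the worst 100/M. This is
the only reading under which the highest-scoring sectors are the hotspots,
and it makes the hotspot set provably equal to the intersection of the
per-role top-k sets (tested against a brute-force O(M²) pairwise-count
oracle). Sectors unsuitable for at least one assemblage member are excluded
from community ranking rather than zero-filled (a flagged alternative),
mirroring the treatment of unsuitable rows/columns in the matrices.

Dispersal kernels are normalized over *settled* propagules per source
region (a flag exposes normalization over released propagules);
displacements are measured between the actual start and end positions, not
sector centroids.

## Synthetic study system

The generator emulates the statistical structure of a semi-enclosed basin
with a dominant cyclonic circulation:

- **Basin**: closed rectangle, 700 × 800 km of sea at 10-km cells inside a
  land ring; the perimeter is exactly 3000 km under the package metric,
  giving 120 sectors of 25 km grouped into 8 equal regions. Sector numbering
  runs clockwise, so cyclonic (counter-clockwise) transport produces
  negative directed offsets. On this closed perimeter, offsets are wrapped
  to the nearest signed value in (−N/2, N/2].
- **Flow**: a single-gyre stream function ψ ∝ −sin(πx̃)sin(πỹ), peak speed
  0.15 m/s (a typical boundary-current magnitude for a marginal sea), exactly
  non-divergent and tangent to the coast. Daily variability (RMS 0.05 m/s)
  enters through random low-order sine modes of ψ, so each daily field is
  also non-divergent. Noise and habitat draws are fully seed-reproducible.
- **Habitat**: depth grows linearly offshore at 3 m/km; per-species habitat
  is (alongshore patches covering ~75% of sectors, drawn from a smoothed
  thresholded noise profile) ∩ (the species' recruitment depth band), which
  confines habitat to the first one or two coastal cell rings, as for
  seagrass-associated species.
- **Assemblage**: four synthetic species spanning the trait space of a
  seagrass-meadow guild — dispersal durations 30, 30, 10 and 7 days with
  staggered release seasons (spring, autumn, early and mid summer) and
  partially overlapping depth ranges.

Default desk-scale runs use 10⁴ propagules per species per year over 3
years, released every 5th day of the season; counts are reported in the run
manifest so binomial sampling error can be judged. Production studies of a
real basin would use far more particles, more years, and measured velocity
archives; the pipeline is unchanged.

What the synthetic system does **not** contain: realistic mesoscale
variability (one gyre plus white-in-time modes, no eddies or fronts), tides,
Stokes drift, vertical shear, alongshore-varying shelf bathymetry, or any
observational habitat structure. Passing tests on this system therefore
demonstrates the correctness of the *computational chain* (release →
advection → classification → matrices → indices → ranking) and
directionally correct physics (retention vs duration, with-flow asymmetry),
not a validated prediction for any real coastline.

## Numerical and degenerate-case conventions

- RK4 substeps clamp to the end of the current field day and to each
  propagule's remaining lifetime, so non-divisor time steps cannot drift.
- Integer release allocation uses largest-remainder rounding, making
  per-sector release counts exactly proportional to suitable area whenever
  the totals divide evenly.
- Empty habitat yields an empty release set with a warning, not an error;
  an empty settled set yields an empty kernel with a warning.
- Geometric means: any zero dominates (community 0) even in the presence of
  +inf; NaN (sector not evaluable for a species) propagates.
- Seeds: one master seed per run; per-species-per-year generators are
  spawned from it (keyed by a CRC of the species name and the year), so
  adding a species never perturbs another species' draws.

## Known limitations

- The equirectangular metric distorts at high latitudes and for domains
  spanning many degrees; a production run at such scales should supply
  velocity fields on a projected grid.
- The lattice sea-distance is a raster approximation; sub-cell coastline
  detail is invisible to it.
- Footprint attribution offshore of a convoluted coastline (e.g. around
  narrow peninsulas) follows straight-line proximity, not water pathways.
- With strict geometric-mean aggregation, community indices are only defined
  where *all* assemblage members have habitat; assemblages with many
  patchy species can leave few evaluable sectors (the score table reports
  how many).
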