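"""Flow matrices and the three connectivity metrics.

For each species and year t, the flow matrix Φ_t counts the propagules
released from source sector i that settled successfully in sink sector j.
Three N x N metrics summarize the T-year stack:

* intensity    I_ij = time mean of φ_ij,t               [propagules / yr]
* effectiveness E_ij = I_ij / suitable area              [propagules / yr / km^2]
* persistence  P_ij = mean(φ) / std(φ)                   [dimensionless]

Persistence is the stabilization coefficient — the reciprocal of the
coefficient of variation of the annual flux series, computed with the
population (1/T) standard deviation over all years including zero years.  A
series that is zero every year has persistence 0 by convention; a constant
nonzero series (zero variance) is perfectly persistent and reported as the
+inf sentinel, never silently capped.

Each sector k additionally gets 3 x 3 functional indicators: its role as a
*retainer* (diagonal flux φ_kk), *source* (off-diagonal row sum) and *sink*
(off-diagonal column sum), each measured by intensity, effectiveness and
persistence of the corresponding annual series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lagrangian import OUTCOME_SETTLED

ROLES = ("retention", "source", "sink")
METRICS = ("intensity", "effectiveness", "persistence")

__all__ = [
    "FlowMatrix",
    "flow_matrix",
    "intensity",
    "effectiveness",
    "persistence",
    "stabilization",
    "active_mask",
    "sector_indicators",
    "indicator_frame",
    "ROLES",
    "METRICS",
]


@dataclass
class FlowMatrix:
    """Stack of annual flow matrices φ_ij,t for one species.

    ``counts`` has shape (T, N, N); rows are source sectors, columns sink
    sectors (both 1-based ids mapped to 0-based axes).
    """

    counts: np.ndarray
    years: list
    species: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[1] != self.counts.shape[2]:
            raise ValueError("counts must have shape (T, N, N)")
        if len(self.years) != self.counts.shape[0]:
            raise ValueError("len(years) must equal the time dimension")
        if np.any(self.counts < 0):
            raise ValueError("flow counts must be non-negative")

    @property
    def n_years(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sectors(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_fates(cls, fates: pd.DataFrame, n_sectors: int, years=None, species: str = "") -> "FlowMatrix":
        """Build the annual stack from a fate table (all years present in it)."""
        if years is None:
            years = sorted(fates["year"].unique())
        counts = np.stack([flow_matrix(fates, y, n_sectors) for y in years])
        return cls(counts=counts, years=list(years), species=species)


def flow_matrix(fates: pd.DataFrame, year: int, n_sectors: int) -> np.ndarray:
    """One year's φ_ij: settled-propagule counts source i -> sink j."""
    st = fates[(fates["outcome"] == OUTCOME_SETTLED) & (fates["year"] == year)]
    m = np.zeros((n_sectors, n_sectors), dtype=np.int64)
    if len(st):
        np.add.at(m, (st["source_sector"].to_numpy() - 1, st["sink_sector"].to_numpy() - 1), 1)
    return m


def intensity(flow: FlowMatrix) -> np.ndarray:
    """Time-mean flux I = (1/T) Σ_t φ_t."""
    return flow.counts.mean(axis=0)


def effectiveness(I: np.ndarray, areas: np.ndarray, denominator: str = "source") -> np.ndarray:
    """Intensity per unit of suitable area.

    ``denominator`` selects which sector's suitable area normalizes each
    connection: "source" divides row i by area_i (donating capacity, the
    default, consistent with releases being uniform over suitable area),
    "sink" divides column j by area_j (receiving capacity).  Connections of
    zero-area sectors are set to 0 (their flux rows/columns are zero anyway).
    """
    areas = np.asarray(areas, dtype=float)
    if np.any(areas < 0):
        raise ValueError("areas must be non-negative")
    I = np.asarray(I, dtype=float)
    safe = np.where(areas > 0, areas, np.inf)
    if denominator == "source":
        return I / safe[:, None]
    if denominator == "sink":
        return I / safe[None, :]
    raise ValueError("denominator must be 'source' or 'sink'")


def stabilization(series: np.ndarray, axis: int = 0) -> np.ndarray:
    """Reciprocal coefficient of variation (population std) along ``axis``.

    Conventions: an all-zero series maps to 0; a constant nonzero series has
    zero variance and maps to +inf (perfectly persistent connection).
    """
    series = np.asarray(series, dtype=float)
    mean = series.mean(axis=axis)
    std = series.std(axis=axis)  # population (1/T)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(std > 0, mean / np.where(std > 0, std, 1.0), np.inf)
    return np.where(mean == 0, 0.0, p)


def persistence(flow: FlowMatrix) -> np.ndarray:
    """Stabilization coefficient of every connection over the year stack."""
    if flow.n_years < 2:
        raise ValueError("persistence needs at least 2 years")
    return stabilization(flow.counts, axis=0)


def active_mask(flow: FlowMatrix) -> np.ndarray:
    """Connections followed by at least one propagule in at least one year."""
    return flow.counts.sum(axis=0) > 0


def sector_indicators(flow: FlowMatrix, areas: np.ndarray) -> np.ndarray:
    """3 roles x 3 metrics per sector; NaN where the sector is unsuitable.

    Returns an (N, 3, 3) array indexed [sector, role, metric] with roles
    (retention, source, sink) and metrics (intensity, effectiveness,
    persistence).  Role series per sector k and year t: retention φ_kk,t;
    source Σ_{j≠k} φ_kj,t; sink Σ_{i≠k} φ_ik,t.  Effectiveness divides each
    role's intensity by sector k's own suitable area (its capacity to donate
    or receive).
    """
    areas = np.asarray(areas, dtype=float)
    if np.any(areas < 0):
        raise ValueError("areas must be non-negative")
    c = flow.counts.astype(float)
    T, N, _ = c.shape
    diag = np.einsum("tkk->tk", c)                 # (T, N)
    src = c.sum(axis=2) - diag                      # off-diagonal row sums
    snk = c.sum(axis=1) - diag                      # off-diagonal column sums
    out = np.full((N, 3, 3), np.nan)
    safe = np.where(areas > 0, areas, np.inf)
    for r, series in enumerate((diag, src, snk)):
        out[:, r, 0] = series.mean(axis=0)
        out[:, r, 1] = out[:, r, 0] / safe
        out[:, r, 2] = stabilization(series, axis=0) if T >= 2 else np.nan
    out[areas <= 0, :, :] = np.nan                  # undefined for unsuitable sectors
    return out


def indicator_frame(ind: np.ndarray, species: str = "", sector_ids=None) -> pd.DataFrame:
    """Tidy (sector, species, role, metric, value) table of sector indicators."""
    N = ind.shape[0]
    ids = np.arange(1, N + 1) if sector_ids is None else np.asarray(sector_ids)
    rows = []
    for k in range(N):
        for r, role in enumerate(ROLES):
            for m, metric in enumerate(METRICS):
                rows.append((int(ids[k]), species, role, metric, ind[k, r, m]))
    return pd.DataFrame(rows, columns=["sector_id", "species", "role", "metric", "value"])
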