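"""Community-level aggregation, percentile ranks and the connectivity score.

Species-specific indicators are aggregated across the assemblage with the
geometric mean, a conservative choice: poor connectivity in one species
cannot be compensated by good connectivity in the others, and a zero for any
species zeroes the community value (short-ranged species thus act as
bottlenecks of community dispersal).

Sectors are then ranked per functional role.  For each role (retention,
source, sink) and each of its three metrics (intensity, effectiveness,
persistence), a sector's metric percentile is the percentage of evaluable
sectors whose value is less than or equal to its own, so the best sector
scores 100 and the worst 100/M.  The *role percentile rank* is the minimum
of the three metric percentiles, and the *community connectivity score* is
the minimum of the three role ranks; sectors with the highest scores can
simultaneously act as retainers, sources and sinks for every species in the
assemblage — the hotspots of community connectivity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import METRICS, ROLES

__all__ = [
    "community_index",
    "community_indicators",
    "community_matrix",
    "metric_percentiles",
    "role_percentile_ranks",
    "connectivity_score",
    "score_table",
    "hotspots",
    "assemblage_compare",
]


def _geomean(stack: np.ndarray, axis: int = 0) -> np.ndarray:
    """Geometric mean with zero-dominance and +inf sentinel propagation.

    Any zero dominates (result 0) even in the presence of infinities; an
    infinite value among all-positive entries yields +inf; NaN propagates
    (sector not evaluable for at least one species).
    """
    a = np.asarray(stack, dtype=float)
    if np.any(a < 0):
        raise ValueError("indicator values must be non-negative")
    has_nan = np.isnan(a).any(axis=axis)
    has_zero = (a == 0).any(axis=axis)
    has_inf = np.isposinf(a).any(axis=axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(np.where(a > 0, a, 1.0))
        logs = np.where(np.isposinf(a), np.inf, logs)
        g = np.exp(np.mean(logs, axis=axis))
    g = np.where(has_inf, np.inf, g)
    g = np.where(has_zero, 0.0, g)
    g = np.where(has_nan, np.nan, g)
    return g


def community_index(values) -> float:
    """Geometric mean of one indicator across the species assemblage."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one species")
    return float(_geomean(v, axis=0))


def community_indicators(per_species: dict) -> np.ndarray:
    """Element-wise geometric mean of (N, 3, 3) indicator arrays.

    ``per_species`` maps species name -> indicator array as produced by
    :func:`metaconn.connectivity.sector_indicators`.  A sector that is not
    evaluable (NaN) for any species is NaN in the community array.
    """
    if not per_species:
        raise ValueError("need at least one species")
    stack = np.stack(list(per_species.values()))
    shapes = {a.shape for a in per_species.values()}
    if len(shapes) != 1:
        raise ValueError("species indicator arrays have mismatched shapes")
    return _geomean(stack, axis=0)


def community_matrix(per_species: dict) -> np.ndarray:
    """Element-wise geometric mean of species N x N metric matrices.

    With intensity matrices as input this is the community intensity matrix;
    its active connections are exactly the pairs active for *every* species
    (zero-dominance).
    """
    if not per_species:
        raise ValueError("need at least one species")
    shapes = {a.shape for a in per_species.values()}
    if len(shapes) != 1:
        raise ValueError("species matrices have mismatched shapes")
    return _geomean(np.stack(list(per_species.values())), axis=0)


def metric_percentiles(values: np.ndarray) -> np.ndarray:
    """Percentile of each sector: % of evaluable sectors with value <= own.

    NaN entries are excluded from the reference distribution (and get NaN
    percentiles).  With M evaluable sectors the best gets 100 and the worst
    100/M; ties share the full count of equal-or-worse sectors.  +inf
    compares greater than every finite value; two infinities tie.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    M = int(ok.sum())
    if M == 0:
        raise ValueError("no evaluable sectors")
    out = np.full(v.shape, np.nan)
    ref = v[ok]
    out[ok] = [100.0 * np.sum(ref <= x) / M for x in ref]
    return out


def role_percentile_ranks(indicators: np.ndarray, role: str) -> np.ndarray:
    """Role percentile rank per sector: min of the role's metric percentiles.

    ``indicators`` is the (N, 3, 3) community indicator array; ``role`` is
    one of "retention", "source", "sink".
    """
    r = ROLES.index(role)
    pcts = np.stack([metric_percentiles(indicators[:, r, m]) for m in range(len(METRICS))])
    return np.min(pcts, axis=0)


def connectivity_score(role_ranks: dict) -> np.ndarray:
    """Community connectivity score: minimum of the three role ranks."""
    missing = [r for r in ROLES if r not in role_ranks]
    if missing:
        raise ValueError(f"missing role ranks: {missing}")
    return np.min(np.stack([np.asarray(role_ranks[r], dtype=float) for r in ROLES]), axis=0)


def score_table(indicators: np.ndarray, threshold_percent: float = 20.0,
                sector_ids=None) -> pd.DataFrame:
    """Per-sector role ranks, score and hotspot flag as a tidy table."""
    ranks = {role: role_percentile_ranks(indicators, role) for role in ROLES}
    score = connectivity_score(ranks)
    N = indicators.shape[0]
    ids = np.arange(1, N + 1) if sector_ids is None else np.asarray(sector_ids)
    return pd.DataFrame(
        {
            "sector_id": ids,
            "retention_rank": ranks["retention"],
            "source_rank": ranks["source"],
            "sink_rank": ranks["sink"],
            "score": score,
            "hotspot": score >= 100.0 - threshold_percent,
        }
    )


def hotspots(scores: np.ndarray, threshold_percent: float, sector_ids=None) -> pd.DataFrame:
    """Sectors whose score falls in the top ``threshold_percent`` %.

    Sorted by score descending, sector id ascending on ties; a threshold of
    0 yields an empty set (no score exceeds 100).
    """
    s = np.asarray(scores, dtype=float)
    N = s.size
    ids = np.arange(1, N + 1) if sector_ids is None else np.asarray(sector_ids)
    cut = 100.0 - threshold_percent
    sel = np.where(np.nan_to_num(s, nan=-np.inf) >= cut)[0] if threshold_percent > 0 else np.array([], dtype=int)
    order = sel[np.lexsort((ids[sel], -s[sel]))]
    return pd.DataFrame({"sector_id": ids[order], "score": s[order]})


def assemblage_compare(matrix_a: np.ndarray, matrix_b: np.ndarray,
                       name_a: str = "A", name_b: str = "B") -> dict:
    """Compare community intensity between two assemblages on the same sectors.

    Returns the per-connection difference (A - B, NaN-safe), per-sector net
    outflow difference, and the connections active in one assemblage only.
    """
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("assemblages evaluated on mismatched sector sets")
    act_a = np.nan_to_num(a) > 0
    act_b = np.nan_to_num(b) > 0
    diff = np.where(np.isnan(a) | np.isnan(b), np.nan, np.nan_to_num(a) - np.nan_to_num(b))
    return {
        "diff": diff,
        "sector_outflow_diff": np.nansum(diff, axis=1),
        "only_in_" + name_a.lower(): np.argwhere(act_a & ~act_b) + 1,
        "only_in_" + name_b.lower(): np.argwhere(act_b & ~act_a) + 1,
        "n_active_" + name_a.lower(): int(act_a.sum()),
        "n_active_" + name_b.lower(): int(act_b.sum()),
    }
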