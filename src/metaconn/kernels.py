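"""Empirical dispersal kernels per source region.

Two complementary views of successful dispersal: the *net displacement*
kernel bins the shortest within-sea distance between a propagule's origin
and its settlement point (Turchin's net displacement), and the *directed
displacement* kernel bins the signed sector offset (destination minus origin
sector number), so dispersal oriented against the sector numbering shows up
as mass at negative offsets.  Both are normalized over settled propagules
within each source region.  A reachability profile reports, per distance
bin, which fraction of candidate destination sectors cannot be reached at
all (unsuitable habitat or outside the domain) — the grey background of the
kernel panels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import SeaDistance, SectorSet
from .lagrangian import OUTCOME_SETTLED

DOT_THRESHOLD = 1e-3  # proportions below this are rendered as dots

__all__ = [
    "net_displacements",
    "net_displacement_kernel",
    "directed_displacement_kernel",
    "reachability_profile",
    "DOT_THRESHOLD",
]


def _settled(fates: pd.DataFrame) -> pd.DataFrame:
    return fates[fates["outcome"] == OUTCOME_SETTLED]


def _region_of_sector(sectors: SectorSet) -> np.ndarray:
    """region id indexed by sector id (index 0 unused)."""
    out = np.zeros(sectors.n + 1, dtype=int)
    out[sectors.ids] = sectors.region_ids
    return out


def net_displacements(fates: pd.DataFrame, sea: SeaDistance) -> np.ndarray:
    """Within-sea origin-to-destination distance (km) of each settled propagule."""
    st = _settled(fates)
    if len(st) == 0:
        return np.array([])
    return sea.pairwise(
        st["start_lon"].to_numpy(), st["start_lat"].to_numpy(),
        st["end_lon"].to_numpy(), st["end_lat"].to_numpy(),
    )


def net_displacement_kernel(
    fates: pd.DataFrame,
    sea: SeaDistance,
    sectors: SectorSet,
    bin_km: float = 25.0,
    n_bins: int | None = None,
) -> pd.DataFrame:
    """Histogram of net displacement per source region, normalized over the
    region's settled propagules.

    Returns a tidy frame (region, bin_lo, bin_hi, proportion, dot) where
    ``dot`` flags proportions below 10^-3 (rendered as dots rather than
    colour in kernel panels).
    """
    st = _settled(fates)
    if len(st) == 0:
        warnings.warn("no settled propagules; empty kernel")
        return pd.DataFrame(columns=["region", "bin_lo", "bin_hi", "proportion", "dot"])
    dist = net_displacements(fates, sea)
    reg_of = _region_of_sector(sectors)
    regions = reg_of[st["source_sector"].to_numpy()]
    if n_bins is None:
        n_bins = max(1, int(np.ceil((dist.max() + 1e-9) / bin_km)))
    edges = np.arange(n_bins + 1) * bin_km
    rows = []
    for r in np.unique(regions):
        d = dist[regions == r]
        h, _ = np.histogram(np.clip(d, 0, edges[-1] - 1e-9), bins=edges)
        p = h / h.sum()
        for b in range(n_bins):
            rows.append((int(r), edges[b], edges[b + 1], p[b], bool(0 < p[b] < DOT_THRESHOLD)))
    return pd.DataFrame(rows, columns=["region", "bin_lo", "bin_hi", "proportion", "dot"])


def directed_displacement_kernel(fates: pd.DataFrame, sectors: SectorSet) -> pd.DataFrame:
    """Histogram of signed sector offsets (destination - origin) per region.

    Negative offsets are movement toward lower sector numbers; on a closed
    coastline offsets are wrapped to the short way round (see
    :meth:`SectorSet.signed_offset`).
    """
    st = _settled(fates)
    if len(st) == 0:
        warnings.warn("no settled propagules; empty kernel")
        return pd.DataFrame(columns=["region", "offset", "proportion", "dot"])
    off = sectors.signed_offset(st["source_sector"].to_numpy(), st["sink_sector"].to_numpy())
    reg_of = _region_of_sector(sectors)
    regions = reg_of[st["source_sector"].to_numpy()]
    rows = []
    lo, hi = int(off.min()), int(off.max())
    for r in np.unique(regions):
        o = off[regions == r]
        vals, counts = np.unique(o, return_counts=True)
        p = dict(zip(vals, counts / counts.sum()))
        for k in range(lo, hi + 1):
            pk = p.get(k, 0.0)
            rows.append((int(r), k, pk, bool(0 < pk < DOT_THRESHOLD)))
    return pd.DataFrame(rows, columns=["region", "offset", "proportion", "dot"])


def reachability_profile(
    sectors: SectorSet,
    habitat,
    sea: SeaDistance | None = None,
    kind: str = "net",
    bin_km: float = 25.0,
    n_bins: int | None = None,
) -> pd.DataFrame:
    """Fraction of destination sectors per distance bin that cannot be reached.

    A destination sector is unreachable when it holds no suitable habitat for
    the species (sectors outside the model domain are simply absent from the
    sector set).  For ``kind="net"`` candidate destinations are binned by the
    within-sea distance between sector midpoints; for ``kind="directed"`` by
    signed sector offset.  Origins are the suitable sectors of each region.
    """
    suit = habitat.suitable_sectors  # (N,) bool, index k-1
    ids = sectors.ids
    regions = sectors.region_ids
    origin_ok = suit
    rows = []
    if kind == "directed":
        n = sectors.n
        if sectors.closed:
            offsets = np.arange(-(n // 2 - 1), n // 2 + 1)
        else:
            offsets = np.arange(-(n - 1), n)
        for r in np.unique(regions[origin_ok]):
            orig = ids[(regions == r) & origin_ok]
            for k in offsets:
                dest = orig + k
                if sectors.closed:
                    dest = (dest - 1) % n + 1
                    ok = np.ones(dest.size, dtype=bool)
                else:
                    ok = (dest >= 1) & (dest <= n)
                total = dest.size
                unreach = np.sum(~ok) + np.sum(~suit[dest[ok] - 1])
                rows.append((int(r), int(k), unreach / total))
        return pd.DataFrame(rows, columns=["region", "offset", "unreachable_fraction"])

    if kind != "net":
        raise ValueError("kind must be 'net' or 'directed'")
    if sea is None:
        raise ValueError("net reachability needs a SeaDistance instance")
    mids = sectors.midpoints
    D = sea.pairwise_matrix(mids[:, 0], mids[:, 1])
    if n_bins is None:
        finite = D[np.isfinite(D)]
        n_bins = max(1, int(np.ceil((finite.max() + 1e-9) / bin_km)))
    edges = np.arange(n_bins + 1) * bin_km
    for r in np.unique(regions[origin_ok]):
        orig_idx = np.where((regions == r) & origin_ok)[0]
        d = D[orig_idx]  # (n_orig, N)
        bins = np.clip((d / bin_km).astype(int), 0, n_bins - 1)
        for b in range(n_bins):
            sel = bins == b
            total = sel.sum()
            if total == 0:
                rows.append((int(r), edges[b], edges[b + 1], 0.0))
                continue
            unreach = np.sum(sel & ~np.broadcast_to(suit, sel.shape))
            rows.append((int(r), edges[b], edges[b + 1], unreach / total))
    return pd.DataFrame(rows, columns=["region", "bin_lo", "bin_hi", "unreachable_fraction"])
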