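"""Stream-network and standing-water bookkeeping.

Strahler ordering of a directed segment network, seasonal stream surface areas
per (region, order) stratum, and the three lentic size classes (<10, [10, 50],
>50 km2) used for lakes and reservoirs. Surface areas are the multiplier that
turns areal fluxes into integrated effluxes, so the inventory is kept strictly
additive: totals are sums over entries, never re-derived.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .carbonate import DomainError

ORDER_MIN, ORDER_MAX = 1, 8

HEADWATER_ORDERS = (1, 2)
INTERMEDIATE_ORDERS = (3, 4, 5)
LARGE_ORDERS = (6, 7, 8)

SIZE_CLASSES = ("small", "medium", "large")


class NetworkError(ValueError):
    """The stream network is not a forest directed toward outlets."""


@dataclass(frozen=True)
class StreamStratum:
    """Total length (km) and seasonal mean widths (m) of one Strahler order
    within one region."""

    region: str
    order: int
    total_length: float
    width_dry: float
    width_wet: float

    def __post_init__(self) -> None:
        if not (ORDER_MIN <= self.order <= ORDER_MAX):
            raise DomainError(f"Strahler order out of range [1, 8]: {self.order}")
        if self.total_length < 0 or self.width_dry < 0 or self.width_wet < 0:
            raise DomainError("lengths and widths must be >= 0")


def classify_lentic(area: float) -> str:
    """Size class of a lake or reservoir from its surface area (km2).

    Boundaries: <10 small, [10, 50] medium (closed on both ends), >50 large.
    """
    if area <= 0:
        raise DomainError(f"lentic area must be > 0 km2: {area}")
    if area < 10.0:
        return "small"
    if area <= 50.0:
        return "medium"
    return "large"


@dataclass(frozen=True)
class LenticBody:
    kind: str  # lake | reservoir
    region: str
    area: float  # km2

    @property
    def size_class(self) -> str:
        return classify_lentic(self.area)


@dataclass
class SurfaceInventory:
    """Water surface areas (m2) keyed by (region, stratum, season).

    ``stratum`` is a Strahler order (int) for streams or a size class string
    for lentic waters; lentic entries use season="annual". Optional
    ``area_sd_m2`` carries the area uncertainty for Monte Carlo propagation.
    """

    table: pd.DataFrame
    period: str = ""
    water_type: str = "stream"

    REQUIRED = ("region", "stratum", "season", "area_m2")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"inventory missing columns: {missing}")
        if (self.table["area_m2"] < 0).any():
            raise DomainError("inventory areas must be >= 0")

    def total_m2(self, season: str | None = None) -> float:
        t = self.table
        if season is not None:
            t = t[t["season"] == season]
        return float(t["area_m2"].sum())

    def total_km2(self, season: str | None = None) -> float:
        return self.total_m2(season) / 1e6

    def area(self, region: str, stratum, season: str) -> float:
        t = self.table
        sel = t[(t["region"] == region) & (t["stratum"] == stratum) & (t["season"] == season)]
        if sel.empty and season != "annual":
            sel = t[(t["region"] == region) & (t["stratum"] == stratum) & (t["season"] == "annual")]
        if sel.empty:
            raise KeyError(f"no inventory entry for {(region, stratum, season)}")
        return float(sel["area_m2"].sum())


def stream_surface_area(
    strata: Iterable[StreamStratum], season: str, period: str = ""
) -> SurfaceInventory:
    """Surface areas per (region, order) for one season: length x seasonal width."""
    rows = []
    for s in strata:
        width = s.width_dry if season == "dry" else s.width_wet
        if width is None or (isinstance(width, float) and np.isnan(width)):
            raise DomainError(f"missing {season} width for region={s.region} order={s.order}")
        rows.append(
            {
                "region": s.region,
                "stratum": s.order,
                "season": season,
                "area_m2": s.total_length * 1000.0 * width,
            }
        )
    return SurfaceInventory(pd.DataFrame(rows), period=period, water_type="stream")


def lentic_surface_inventory(
    bodies: Iterable[LenticBody], kind: str, period: str = ""
) -> SurfaceInventory:
    """Annual surface areas of lakes or reservoirs per (region, size class)."""
    acc: dict[tuple[str, str], float] = defaultdict(float)
    for b in bodies:
        if b.kind != kind:
            continue
        acc[(b.region, b.size_class)] += b.area * 1e6
    rows = [
        {"region": r, "stratum": sc, "season": "annual", "area_m2": a}
        for (r, sc), a in sorted(acc.items())
    ]
    return SurfaceInventory(pd.DataFrame(rows), period=period, water_type=kind)


def strahler_order(edges: Mapping[str, str | None]) -> dict[str, int]:
    """Strahler order per segment of a forest directed toward outlets.

    ``edges`` maps segment_id -> downstream segment_id (None for outlets).
    Leaves (no upstream segment) are order 1; a segment whose upstream
    neighbours have maximum order m takes order m+1 when two or more of them
    reach m, else m. Cycles or dangling downstream references raise
    NetworkError.
    """
    upstream: dict[str, list[str]] = defaultdict(list)
    indeg: dict[str, int] = {seg: 0 for seg in edges}
    for seg, down in edges.items():
        if down is None:
            continue
        if down not in edges:
            raise NetworkError(f"segment {seg} drains to unknown segment {down}")
        upstream[down].append(seg)
        indeg[down] += 1

    order: dict[str, int] = {}
    queue = [seg for seg, d in indeg.items() if d == 0]
    remaining = dict(indeg)
    processed = 0
    while queue:
        seg = queue.pop()
        ups = upstream.get(seg, [])
        if not ups:
            order[seg] = 1
        else:
            m = max(order[u] for u in ups)
            order[seg] = m + 1 if sum(order[u] == m for u in ups) >= 2 else m
        processed += 1
        down = edges[seg]
        if down is not None:
            remaining[down] -= 1
            if remaining[down] == 0:
                queue.append(down)
    if processed != len(edges):
        raise NetworkError("cycle detected in stream network")
    return order


def order_group(order: int) -> str:
    """Headwater (1-2), intermediate (3-5) or large (6-8) stream group."""
    if order in HEADWATER_ORDERS:
        return "headwater"
    if order in INTERMEDIATE_ORDERS:
        return "intermediate"
    if order in LARGE_ORDERS:
        return "large"
    raise DomainError(f"Strahler order out of range [1, 8]: {order}")
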