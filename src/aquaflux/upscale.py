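"""Stratified upscaling of areal fluxes to regional and national effluxes.

Each (region, stratum, season) cell contributes

    efflux [Tg C yr-1] = F_mean * SA * N * 12 / 1e15

with F_mean the stratum-mean areal flux (mmol m-2 d-1), SA the water surface
area (m2), N the ice-free days of that season, and 12 g/mol the molar mass of
carbon. Strata are Strahler orders 1-8 for streams and the three size classes
for lakes/reservoirs (annual areas, seasonal flux means). Totals are plain
sums, so the national estimate equals the sum of regional estimates exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .hydrography import (
    HEADWATER_ORDERS,
    INTERMEDIATE_ORDERS,
    LARGE_ORDERS,
    SurfaceInventory,
)

logger = logging.getLogger(__name__)

MG_C_PER_MMOL_CO2 = 12.0
MG_PER_TG = 1e15

FLUX_COLUMNS = ("region", "stratum", "season", "mean_F")


@dataclass(frozen=True)
class StratumFlux:
    """Mean areal flux of one (region, stratum, season) cell, with the spread
    and count of the site-level values behind it."""

    region: str
    stratum: object
    season: str
    mean_F: float  # mmol m-2 d-1
    sd_F: float = 0.0
    n_sites: int = 1

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.sd_F < 0:
            raise ValueError("sd_F must be >= 0")


@dataclass(frozen=True)
class EffluxEstimate:
    """An integrated efflux (Tg C yr-1) with optional uncertainty summaries."""

    value: float
    sd: float = 0.0
    ci5: float | None = None
    ci95: float | None = None
    scope: tuple = ()


class MissingStratumError(ValueError):
    """Inventory cells with area but no flux entry and no usable fallback."""


def cell_efflux(mean_F: float, area_m2: float, days: float) -> float:
    """Efflux of a single stratum cell in Tg C per year."""
    return mean_F * area_m2 * days * MG_C_PER_MMOL_CO2 / MG_PER_TG


def _flux_frame(fluxes) -> pd.DataFrame:
    if isinstance(fluxes, pd.DataFrame):
        df = fluxes.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "region": f.region,
                    "stratum": f.stratum,
                    "season": f.season,
                    "mean_F": f.mean_F,
                    "sd_F": f.sd_F,
                    "n_sites": f.n_sites,
                }
                for f in fluxes
            ]
        )
    missing = [c for c in FLUX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"flux table missing columns: {missing}")
    if "sd_F" not in df.columns:
        df["sd_F"] = 0.0
    return df


def fill_missing_strata(flux_df: pd.DataFrame, areas: SurfaceInventory) -> pd.DataFrame:
    """Fill inventory cells that lack a flux entry.

    Stream strata inherit the mean of the adjacent Strahler orders within the
    region (same season), else the regional seasonal mean; lentic size classes
    go straight to the regional mean. Unfillable gaps raise
    MissingStratumError listing every gap.
    """
    df = flux_df.copy()
    have = {(r.region, r.stratum, r.season) for r in df.itertuples()}
    gaps, fills = [], []
    for row in areas.table.itertuples():
        if row.area_m2 <= 0:
            continue
        seasons = ("dry", "wet") if row.season == "annual" else (row.season,)
        for season in seasons:
            key = (row.region, row.stratum, season)
            if key in have:
                continue
            have.add(key)
            candidates = pd.Series(dtype=float)
            if isinstance(row.stratum, (int,)) or (
                isinstance(row.stratum, float) and float(row.stratum).is_integer()
            ):
                o = int(row.stratum)
                adj = df[
                    (df["region"] == row.region)
                    & (df["season"] == season)
                    & (df["stratum"].isin([o - 1, o + 1]))
                ]
                candidates = adj["mean_F"]
            if candidates.empty:
                reg = df[(df["region"] == row.region) & (df["season"] == season)]
                candidates = reg["mean_F"]
            if candidates.empty:
                gaps.append(key)
                continue
            logger.info("filled missing stratum flux %s from %d neighbours", key, len(candidates))
            fills.append(
                {
                    "region": row.region,
                    "stratum": row.stratum,
                    "season": season,
                    "mean_F": float(candidates.mean()),
                    "sd_F": float(candidates.std(ddof=0)) if len(candidates) > 1 else 0.0,
                    "n_sites": 1,
                }
            )
    if gaps:
        raise MissingStratumError(f"no flux and no fallback for strata: {gaps}")
    if fills:
        df = pd.concat([df, pd.DataFrame(fills)], ignore_index=True)
    return df


def integrate_efflux(
    fluxes,
    areas: SurfaceInventory,
    ice_free_days: Mapping[str, Mapping[str, float]],
    fill_missing: bool = True,
) -> pd.DataFrame:
    """Per-cell efflux table joining stratum fluxes, areas and ice-free days.

    ``ice_free_days`` maps region -> {season: days}. Lentic (annual) inventory
    entries pair with both seasonal flux means.
    """
    df = _flux_frame(fluxes)
    if fill_missing:
        df = fill_missing_strata(df, areas)
    rows = []
    for r in df.itertuples():
        try:
            area = areas.area(r.region, r.stratum, r.season)
        except KeyError:
            continue  # sampled stratum with no mapped surface -> no contribution
        days = ice_free_days[r.region][r.season]
        rows.append(
            {
                "region": r.region,
                "stratum": r.stratum,
                "season": r.season,
                "mean_F": r.mean_F,
                "sd_F": getattr(r, "sd_F", 0.0),
                "area_m2": area,
                "days": days,
                "efflux_TgC": cell_efflux(r.mean_F, area, days),
            }
        )
    if not rows:
        raise ValueError("no overlapping (region, stratum, season) cells between fluxes and areas")
    return pd.DataFrame(rows)


def _estimate(cells: pd.DataFrame, scope: tuple) -> EffluxEstimate:
    return EffluxEstimate(value=float(cells["efflux_TgC"].sum()), scope=scope)


def efflux_streams(
    fluxes, areas: SurfaceInventory, ice_free_days: Mapping[str, Mapping[str, float]]
) -> tuple[EffluxEstimate, dict[str, EffluxEstimate], pd.DataFrame]:
    """National and per-region stream/river effluxes plus the per-cell table."""
    cells = integrate_efflux(fluxes, areas, ice_free_days)
    regional = {
        region: _estimate(sub, scope=(areas.period, region, "streams"))
        for region, sub in cells.groupby("region")
    }
    national = _estimate(cells, scope=(areas.period, "national", "streams"))
    return national, regional, cells


def efflux_lentic(
    fluxes, areas: SurfaceInventory, ice_free_days: Mapping[str, Mapping[str, float]]
) -> tuple[EffluxEstimate, dict[str, EffluxEstimate], pd.DataFrame]:
    """National and per-region lentic effluxes (size-class strata, annual areas)."""
    cells = integrate_efflux(fluxes, areas, ice_free_days)
    regional = {
        region: _estimate(sub, scope=(areas.period, region, areas.water_type))
        for region, sub in cells.groupby("region")
    }
    national = _estimate(cells, scope=(areas.period, "national", areas.water_type))
    return national, regional, cells


def per_order_efflux(cells: pd.DataFrame) -> dict[int, float]:
    """National efflux per Strahler order from a stream per-cell table."""
    out = cells.groupby("stratum")["efflux_TgC"].sum()
    return {int(k): float(v) for k, v in out.items()}


def order_group_shares(per_order: Mapping[int, float]) -> dict[str, float]:
    """Fractions of riverine efflux from headwater (1-2), intermediate (3-5)
    and large (6-8) streams; fractions sum to 1."""
    total = sum(per_order.values())
    if total == 0:
        raise ValueError("total efflux is zero; shares undefined")
    groups = {
        "headwater": HEADWATER_ORDERS,
        "intermediate": INTERMEDIATE_ORDERS,
        "large": LARGE_ORDERS,
    }
    return {
        name: sum(per_order.get(o, 0.0) for o in orders) / total
        for name, orders in groups.items()
    }
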