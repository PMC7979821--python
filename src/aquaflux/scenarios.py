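"""Period scenarios: national study conditions for the 1980s and 2010s.

The two study periods are defined by published national bookkeeping numbers --
seasonal stream surface areas, annual lake and reservoir areas, regional
efflux totals with their SDs, and the headwater share of riverine efflux.
These printed values are *inputs* to the package: ``gen_scenario`` expands
them into full stratified fixtures (per region / Strahler order / size class /
season) whose aggregation reproduces the regional and national totals exactly,
which is what makes the upscaling, uncertainty and budget stages testable
end-to-end without the original site-level dataset.

Construction: surface areas are split across regions with fixed plausible
shares and across orders with a Horton-like geometric profile; per-order
efflux shares follow a geometric profile whose ratio is solved so the
headwater (order 1-2) share equals the period's printed share; the stratum
mean fluxes are then back-solved from the stratified sum given areas and
ice-free days, with a fixed wet/dry flux ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .carbonate import REGIONS
from .hydrography import ORDER_MAX, SIZE_CLASSES, SurfaceInventory

PERIODS = ("1980s", "2010s")

#: atmospheric pCO2 reference per period, uatm (era-appropriate global means)
ATM_PCO2 = {"1980s": 340.0, "2010s": 400.0}

#: regional efflux totals (value, sd) in Tg C yr-1 per water type and period
REGIONAL_EFFLUX = {
    "1980s": {
        "rivers": {
            "GreaterPearl": (23.8, 12.7),
            "Yangtze": (46.0, 24.4),
            "HuangHuaiHai": (15.7, 8.0),
            "NEChina": (16.0, 5.4),
            "NWChina": (11.2, 8.5),
            "TibetanPlateau": (15.8, 7.4),
        },
        "lakes": {
            "GreaterPearl": (0.2, 0.1),
            "Yangtze": (2.1, 1.1),
            "HuangHuaiHai": (0.9, 0.2),
            "NEChina": (1.3, 0.2),
            "NWChina": (0.7, 0.2),
            "TibetanPlateau": (2.1, 1.0),
        },
        "reservoirs": {
            "GreaterPearl": (0.3, 0.1),
            "Yangtze": (0.7, 0.3),
            "HuangHuaiHai": (0.5, 0.1),
            "NEChina": (0.5, 0.1),
            "NWChina": (0.1, 0.02),
            "TibetanPlateau": (0.03, 0.01),
        },
    },
    "2010s": {
        "rivers": {
            "GreaterPearl": (12.2, 4.6),
            "Yangtze": (29.9, 15.3),
            "HuangHuaiHai": (9.2, 3.8),
            "NEChina": (11.0, 6.1),
            "NWChina": (4.9, 2.3),
            "TibetanPlateau": (18.6, 7.9),
        },
        "lakes": {
            "GreaterPearl": (0.1, 0.1),
            "Yangtze": (1.1, 0.4),
            "HuangHuaiHai": (0.8, 0.4),
            "NEChina": (1.4, 0.3),
            "NWChina": (1.2, 0.5),
            "TibetanPlateau": (3.8, 1.1),
        },
        "reservoirs": {
            "GreaterPearl": (0.8, 0.5),
            "Yangtze": (1.0, 0.3),
            "HuangHuaiHai": (0.8, 0.4),
            "NEChina": (0.6, 0.2),
            "NWChina": (0.4, 0.1),
            "TibetanPlateau": (0.07, 0.02),
        },
    },
}

#: published national subtotals (value, sd) per water type; the printed
#: regional values carry one-decimal rounding, so each regional column is
#: rescaled by <0.2% to make its sum match the published subtotal exactly
#: (the rescaled values still round to the printed regional figures)
SUBTOTAL_EFFLUX = {
    "1980s": {"rivers": (128.6, 31.3), "lakes": (7.3, 1.5), "reservoirs": (2.1, 0.3)},
    "2010s": {"rivers": (85.8, 19.4), "lakes": (8.4, 1.4), "reservoirs": (3.7, 0.7)},
}


def regional_efflux_unrounded(period: str, kind: str) -> dict[str, tuple[float, float]]:
    """Regional (value, sd) pairs rescaled so values sum to the printed subtotal."""
    column = REGIONAL_EFFLUX[period][kind]
    factor = SUBTOTAL_EFFLUX[period][kind][0] / sum(v for v, _ in column.values())
    return {r: (v * factor, sd) for r, (v, sd) in column.items()}


#: national water surface areas (km2) with SDs
NATIONAL_AREAS_KM2 = {
    "1980s": {
        "stream_dry": (55_488.0, 12_886.0),
        "stream_wet": (65_076.0, 14_357.0),
        "lakes": (79_196.0, 6_415.0),
        "reservoirs": (14_772.0, 1_196.0),
    },
    "2010s": {
        "stream_dry": (51_003.0, 14_439.0),
        "stream_wet": (58_279.0, 15_027.0),
        "lakes": (82_570.0, 6_688.0),
        "reservoirs": (25_616.0, 2_075.0),
    },
}

#: published fraction of riverine efflux from headwater (order 1-2) streams
HEADWATER_EFFLUX_SHARE = {"1980s": 0.55, "2010s": 0.61}

#: terrestrial carbon sink ranges (Tg C yr-1) used for the offset comparison:
#: 1980s from a biomass-accumulation mean +/- SD of 177 +/- 73; 2010s from the
#: updated 2000s range used as a lower-limit estimate.
TERRESTRIAL_SINK = {"1980s": (104.0, 250.0), "2010s": (201.0, 250.0)}

#: regional shares of national stream surface area (design choice, fixed)
STREAM_REGION_SHARE = {
    "GreaterPearl": 0.12,
    "Yangtze": 0.30,
    "HuangHuaiHai": 0.13,
    "NEChina": 0.15,
    "NWChina": 0.12,
    "TibetanPlateau": 0.18,
}

#: regional shares of national lake / reservoir surface area; more than half
#: of the lake surface sits on the Tibetan Plateau
LAKE_REGION_SHARE = {
    "GreaterPearl": 0.02,
    "Yangtze": 0.18,
    "HuangHuaiHai": 0.08,
    "NEChina": 0.10,
    "NWChina": 0.10,
    "TibetanPlateau": 0.52,
}
RESERVOIR_REGION_SHARE = {
    "GreaterPearl": 0.18,
    "Yangtze": 0.30,
    "HuangHuaiHai": 0.22,
    "NEChina": 0.15,
    "NWChina": 0.13,
    "TibetanPlateau": 0.02,
}

#: per-order share of stream surface area: geometric with ratio 0.8788, giving
#: a headwater (order 1-2) area share of ~35% (within the published 34-38%)
ORDER_AREA_RATIO = 0.8788

#: lentic size-class shares of area and of efflux; the efflux concentrates in
#: small water bodies, so the implied areal flux declines with size class
LENTIC_AREA_SHARE = {"small": 0.30, "medium": 0.30, "large": 0.40}
LENTIC_EFFLUX_SHARE = {"small": 0.45, "medium": 0.30, "large": 0.25}

#: wet-season areal fluxes exceed dry-season fluxes by this factor
WET_DRY_FLUX_RATIO = 1.35

#: season lengths (days): dry Nov-Apr, wet May-Oct
SEASON_DAYS = {"dry": 181, "wet": 184}

#: ice-free days per region and season; cold-winter regions lose part of the
#: dry season, the high plateau part of both seasons
DEFAULT_ICE_FREE_DAYS = {
    "GreaterPearl": {"dry": 181, "wet": 184},
    "Yangtze": {"dry": 181, "wet": 184},
    "HuangHuaiHai": {"dry": 165, "wet": 184},
    "NEChina": {"dry": 100, "wet": 184},
    "NWChina": {"dry": 130, "wet": 184},
    "TibetanPlateau": {"dry": 90, "wet": 165},
}


def geometric_shares(n: int, ratio: float) -> np.ndarray:
    w = ratio ** np.arange(n)
    return w / w.sum()


def order_efflux_shares(headwater_share: float, n_orders: int = ORDER_MAX) -> np.ndarray:
    """Geometric per-order efflux shares whose order 1-2 sum equals the target."""

    def head(r: float) -> float:
        s = geometric_shares(n_orders, r)
        return s[0] + s[1]

    ratio = brentq(lambda r: head(r) - headwater_share, 1e-6, 1.0 - 1e-9)
    return geometric_shares(n_orders, ratio)


@dataclass
class ScenarioBundle:
    """Everything one period's upscaling run needs, in pipeline-ready tables."""

    period: str
    atm_pco2: float
    stream_fluxes: pd.DataFrame
    stream_inventory: SurfaceInventory
    lake_fluxes: pd.DataFrame
    lake_inventory: SurfaceInventory
    reservoir_fluxes: pd.DataFrame
    reservoir_inventory: SurfaceInventory
    ice_free_days: dict
    climate: pd.DataFrame

    def write_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.stream_fluxes.to_csv(outdir / "stream_fluxes.csv", index=False)
        self.stream_inventory.table.to_csv(outdir / "stream_inventory.csv", index=False)
        self.lake_fluxes.to_csv(outdir / "lake_fluxes.csv", index=False)
        self.lake_inventory.table.to_csv(outdir / "lake_inventory.csv", index=False)
        self.reservoir_fluxes.to_csv(outdir / "reservoir_fluxes.csv", index=False)
        self.reservoir_inventory.table.to_csv(outdir / "reservoir_inventory.csv", index=False)
        self.climate.to_csv(outdir / "climate.csv", index=False)
        ice = pd.DataFrame(
            [
                {"region": r, "season": s, "ice_free_days": d}
                for r, seasons in self.ice_free_days.items()
                for s, d in seasons.items()
            ]
        )
        ice.to_csv(outdir / "ice_free_days.csv", index=False)


def _stream_tables(period: str, ice_free: dict) -> tuple[pd.DataFrame, SurfaceInventory]:
    areas = NATIONAL_AREAS_KM2[period]
    order_shares = geometric_shares(ORDER_MAX, ORDER_AREA_RATIO)
    efflux_shares = order_efflux_shares(HEADWATER_EFFLUX_SHARE[period])
    regional = regional_efflux_unrounded(period, "rivers")
    inv_rows, flux_rows = [], []
    for region in REGIONS:
        rshare = STREAM_REGION_SHARE[region]
        total, sd = regional[region]
        rel_sd = sd / total
        for o in range(1, ORDER_MAX + 1):
            sa = {
                s: areas[f"stream_{s}"][0] * 1e6 * rshare * order_shares[o - 1]
                for s in ("dry", "wet")
            }
            for s in ("dry", "wet"):
                inv_rows.append(
                    {"region": region, "stratum": o, "season": s, "area_m2": sa[s]}
                )
            target = total * efflux_shares[o - 1]  # Tg C yr-1 for this (region, order)
            denom = (
                sa["dry"] * ice_free[region]["dry"]
                + WET_DRY_FLUX_RATIO * sa["wet"] * ice_free[region]["wet"]
            ) * 12.0 / 1e15
            f_dry = target / denom
            for s, f in (("dry", f_dry), ("wet", WET_DRY_FLUX_RATIO * f_dry)):
                flux_rows.append(
                    {
                        "region": region,
                        "stratum": o,
                        "season": s,
                        "mean_F": f,
                        "sd_F": f * rel_sd,
                        "n_sites": 25,
                    }
                )
    inv = SurfaceInventory(pd.DataFrame(inv_rows), period=period, water_type="stream")
    return pd.DataFrame(flux_rows), inv


def _lentic_tables(
    period: str, kind: str, region_share: dict, ice_free: dict
) -> tuple[pd.DataFrame, SurfaceInventory]:
    total_area = NATIONAL_AREAS_KM2[period][kind][0] * 1e6
    regional = regional_efflux_unrounded(period, kind)
    inv_rows, flux_rows = [], []
    for region in REGIONS:
        total, sd = regional[region]
        rel_sd = sd / total
        for sc in SIZE_CLASSES:
            sa = total_area * region_share[region] * LENTIC_AREA_SHARE[sc]
            inv_rows.append({"region": region, "stratum": sc, "season": "annual", "area_m2": sa})
            target = total * LENTIC_EFFLUX_SHARE[sc]
            denom = (
                sa
                * (
                    ice_free[region]["dry"]
                    + WET_DRY_FLUX_RATIO * ice_free[region]["wet"]
                )
                * 12.0
                / 1e15
            )
            f_dry = target / denom
            for s, f in (("dry", f_dry), ("wet", WET_DRY_FLUX_RATIO * f_dry)):
                flux_rows.append(
                    {
                        "region": region,
                        "stratum": sc,
                        "season": s,
                        "mean_F": f,
                        "sd_F": f * rel_sd,
                        "n_sites": 10,
                    }
                )
    inv = SurfaceInventory(pd.DataFrame(inv_rows), period=period, water_type=kind)
    return pd.DataFrame(flux_rows), inv


def gen_scenario(period: str, seed: int | None = 0) -> ScenarioBundle:
    """Build the full fixture bundle for one period.

    Deterministic given the period (the seed only feeds the wind climatology
    noise); national stream, lake and reservoir areas equal the published
    period values and the stratified efflux sums equal the regional totals.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {PERIODS}")
    ice_free = DEFAULT_ICE_FREE_DAYS
    stream_fluxes, stream_inv = _stream_tables(period, ice_free)
    lake_fluxes, lake_inv = _lentic_tables(period, "lakes", LAKE_REGION_SHARE, ice_free)
    res_fluxes, res_inv = _lentic_tables(period, "reservoirs", RESERVOIR_REGION_SHARE, ice_free)

    rng = np.random.default_rng(seed)
    climate = pd.DataFrame(
        [
            {
                "region": region,
                "season": season,
                "wind_m_s": float(max(0.1, rng.normal(2.2, 0.3))),
                "ice_free_days": ice_free[region][season],
            }
            for region in REGIONS
            for season in ("dry", "wet")
        ]
    )
    return ScenarioBundle(
        period=period,
        atm_pco2=ATM_PCO2[period],
        stream_fluxes=stream_fluxes,
        stream_inventory=stream_inv,
        lake_fluxes=lake_fluxes,
        lake_inventory=lake_inv,
        reservoir_fluxes=res_fluxes,
        reservoir_inventory=res_inv,
        ice_free_days=ice_free,
        climate=climate,
    )


def annual_mean_stream_area_km2(period: str) -> float:
    """Season-mean national stream surface area, km2."""
    a = NATIONAL_AREAS_KM2[period]
    return (a["stream_dry"][0] + a["stream_wet"][0]) / 2.0


def total_inland_water_area_km2(period: str) -> float:
    """Season-mean streams plus annual lakes and reservoirs, km2."""
    a = NATIONAL_AREAS_KM2[period]
    return annual_mean_stream_area_km2(period) + a["lakes"][0] + a["reservoirs"][0]
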