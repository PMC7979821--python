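"""Synthetic gauge, network and lentic data with the study's statistical shape.

The generators emulate the population structure the upscaling assumes: a
right-skewed stream pCO2 distribution (national mean near 2.8e3 uatm),
areal fluxes that decline with Strahler order, Horton-like segment-number
decay with order, a headwater area share near one third, wet-season fluxes
exceeding dry-season ones, and a lentic pCO2 population with about one fifth
of sites undersaturated. All draws come from a caller-supplied seed and are
bit-reproducible.

Gauge chemistry is generated *backwards*: each site draws a target areal flux
from its order's profile, the implied pCO2 follows from the site's gas
transfer velocity, and pH is then solved from (pCO2, alkalinity, temperature)
through the carbonate cubic, so running the forward pipeline on the tables
recovers the target fluxes exactly up to sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .carbonate import REGIONS, ph_from_pco2
from .flux import CM_PER_H_TO_M_PER_D
from .gas_transfer import (
    DEFAULT_REGISTRY,
    M_PER_DAY_TO_CM_PER_H,
    k600_lentic,
    schmidt_number,
)
from .hydrography import ORDER_MAX
from .scenarios import ATM_PCO2, NATIONAL_AREAS_KM2


@dataclass(frozen=True)
class GaugeProfile:
    """Order-structured defaults for the gauge generator.

    The headwater V*S product is set so the order-1 mean k600 is ~43 cm/h and
    declines geometrically downstream; per-order target fluxes decline
    linearly from ``F_head`` to ``F_tail`` (average step ~96 mmol m-2 d-1
    over orders 1-8). Alkalinity is lognormal around 1800 ueq/L.
    """

    velocity_head: float = 0.30  # m/s, order-1 mean
    velocity_ratio: float = 1.08  # velocity grows mildly downstream
    slope_head: float = 0.0115  # m/m, order-1 mean
    slope_ratio: float = 0.60  # V*S declines by ~0.65 per order
    width_head: float = 4.0  # m
    width_ratio: float = 1.9
    depth_head: float = 0.30  # m
    depth_ratio: float = 1.33
    F_head: float = 700.0  # mmol m-2 d-1, order-1 target mean
    F_tail: float = 110.0  # order-8 target mean
    wet_dry_ratio: float = 1.35  # wet-season flux excess (within 22-48%)
    site_sigma: float = 0.30  # lognormal spread of site flux targets
    obs_sigma: float = 0.20  # lognormal spread of repeat observations
    hydraulics_sigma: float = 0.25  # lognormal spread of site V and S
    alkalinity_median: float = 1800.0  # ueq/L
    alkalinity_sigma: float = 0.45
    temp_mean: float = 16.0  # deg C annual mean
    temp_amplitude: float = 9.0  # seasonal half-range


#: sampling effort per order: headwaters dominate gauge coverage
SITES_PER_ORDER = (14, 12, 10, 8, 6, 5, 4, 3)


def _lognoise(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Mean-one lognormal multiplicative noise."""
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def gen_gauges(
    profile: GaugeProfile | None = None,
    period: str = "2010s",
    n_sites_per_order: tuple[int, ...] = SITES_PER_ORDER,
    n_obs_per_site: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gauge chemistry and hydraulics tables for all regions and orders.

    Returns (chemistry, hydraulics). Chemistry rows are per observation
    (site_id, region, order, season, month, pH, alkalinity_ueq_L, temp_C);
    hydraulics rows are per site (velocity_m_s, slope, depth_m, width_m,
    discharge_m3_s).
    """
    p = profile or GaugeProfile()
    if n_obs_per_site < 1:
        raise ValueError("n_obs_per_site must be >= 1")
    rng = np.random.default_rng(seed)
    atm = ATM_PCO2[period]
    raymond_a, raymond_b = DEFAULT_REGISTRY["raymond"].coeffs

    step = (p.F_head - p.F_tail) / (ORDER_MAX - 1)
    chem_rows, hydr_rows = [], []
    for region in REGIONS:
        for order in range(1, ORDER_MAX + 1):
            n_sites = n_sites_per_order[order - 1]
            F_order = p.F_head - step * (order - 1)
            v_mean = p.velocity_head * p.velocity_ratio ** (order - 1)
            s_mean = p.slope_head * p.slope_ratio ** (order - 1)
            for i in range(n_sites):
                site_id = f"{region}-o{order}-s{i:03d}"
                velocity = v_mean * _lognoise(rng, p.hydraulics_sigma, None)
                slope = s_mean * _lognoise(rng, p.hydraulics_sigma, None)
                width = p.width_head * p.width_ratio ** (order - 1) * _lognoise(rng, 0.2, None)
                depth = p.depth_head * p.depth_ratio ** (order - 1) * _lognoise(rng, 0.2, None)
                hydr_rows.append(
                    {
                        "site_id": site_id,
                        "region": region,
                        "order": order,
                        "velocity_m_s": velocity,
                        "slope": slope,
                        "depth_m": depth,
                        "width_m": width,
                        "discharge_m3_s": velocity * width * depth,
                    }
                )
                k600 = (raymond_a * velocity * slope + raymond_b) * M_PER_DAY_TO_CM_PER_H
                F_site = F_order * _lognoise(rng, p.site_sigma, None)
                alk = p.alkalinity_median * rng.lognormal(0.0, p.alkalinity_sigma)

                months = rng.integers(1, 13, n_obs_per_site)
                wet = (months >= 5) & (months <= 10)
                temp = np.clip(
                    p.temp_mean
                    - p.temp_amplitude * np.cos(2.0 * np.pi * (months - 1) / 12.0)
                    + rng.normal(0.0, 1.5, n_obs_per_site),
                    0.5,
                    38.0,
                )
                F_obs = (
                    F_site
                    * np.where(wet, p.wet_dry_ratio, 1.0)
                    * _lognoise(rng, p.obs_sigma, n_obs_per_site)
                )
                sc = np.array([schmidt_number(t) for t in temp])
                k_obs = k600 * (sc / 600.0) ** -0.5
                # KH at observation temperature (Plummer & Busenberg fit)
                T = temp + 273.15
                kh = 10.0 ** (
                    108.3865 + 0.01985076 * T - 6919.53 / T - 40.45154 * np.log10(T) + 669365.0 / T**2
                )
                delta = F_obs / (k_obs * CM_PER_H_TO_M_PER_D * kh)
                pco2 = np.clip(delta + atm, 112.0, 29_096.0)
                ph = ph_from_pco2(pco2, np.full(n_obs_per_site, alk), temp)
                for j in range(n_obs_per_site):
                    chem_rows.append(
                        {
                            "site_id": site_id,
                            "region": region,
                            "order": order,
                            "season": "wet" if wet[j] else "dry",
                            "month": int(months[j]),
                            "pH": float(ph[j]),
                            "alkalinity_ueq_L": float(alk),
                            "temp_C": float(temp[j]),
                        }
                    )
    return pd.DataFrame(chem_rows), pd.DataFrame(hydr_rows)


def gen_network(
    horton_ratio: int = 4,
    max_order: int = ORDER_MAX,
    region: str = "Yangtze",
    seed: int = 0,
    length_head_km: float = 1.6,
    length_ratio: float = 1.85,
    width_head_m: float = 4.0,
    width_ratio: float = 1.9,
    wet_width_factor: float = 1.17,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Horton-like synthetic network: edge list plus per-order strata.

    Segment counts decay geometrically with order (count(o) =
    horton_ratio^(max_order-o)); each order-o segment receives ``horton_ratio``
    order-(o-1) tributaries, so Strahler ordering of the edge list reproduces
    the declared orders. Default geometry puts the headwater (order 1-2) area
    share near 35%.
    """
    if horton_ratio <= 1:
        raise ValueError("horton_ratio must be > 1")
    rng = np.random.default_rng(seed)
    edges, next_id = [], [0]

    def new_segment(order: int, downstream: str | None) -> str:
        seg = f"{region}-{next_id[0]:06d}"
        next_id[0] += 1
        length = length_head_km * length_ratio ** (order - 1) * _lognoise(rng, 0.25, None)
        edges.append(
            {
                "segment_id": seg,
                "downstream_id": downstream if downstream is not None else "",
                "length_km": float(length),
                "region": region,
                "order": order,
            }
        )
        if order > 1:
            for _ in range(horton_ratio):
                new_segment(order - 1, seg)
        return seg

    new_segment(max_order, None)
    edge_df = pd.DataFrame(edges)

    strata = (
        edge_df.groupby("order")["length_km"]
        .sum()
        .reset_index()
        .rename(columns={"length_km": "total_length_km"})
    )
    strata["region"] = region
    strata["width_dry_m"] = width_head_m * width_ratio ** (strata["order"] - 1)
    strata["width_wet_m"] = strata["width_dry_m"] * wet_width_factor
    return edge_df, strata


def gen_lentic(
    period: str = "2010s",
    n_bodies: int = 400,
    n_pco2_sites: int = 500,
    undersaturated_fraction: float = 0.21,
    pco2_sigma: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lentic inventory and site pCO2 samples for one period.

    Body areas are lognormal spanning the three size classes, rescaled so the
    national lake and reservoir totals equal the period's published areas
    (which makes the 1980s->2010s reservoir change reproduce the published
    73% increase). Site pCO2 is lognormal with its median placed so the
    probability of undersaturation (pCO2 below the atmospheric reference)
    equals ``undersaturated_fraction``.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    atm = ATM_PCO2[period]

    n_res = n_bodies // 3
    kinds = np.array(["lake"] * (n_bodies - n_res) + ["reservoir"] * n_res)
    regions = rng.choice(REGIONS, n_bodies)
    areas = rng.lognormal(np.log(2.0), 1.6, n_bodies)  # km2
    bodies = pd.DataFrame(
        {"kind": kinds, "region": regions, "area_km2": areas}
    )
    for kind, key in (("lake", "lakes"), ("reservoir", "reservoirs")):
        mask = bodies["kind"] == kind
        target = NATIONAL_AREAS_KM2[period][key][0]
        bodies.loc[mask, "area_km2"] *= target / bodies.loc[mask, "area_km2"].sum()

    # median such that P(pCO2 < atm) = undersaturated_fraction
    median = atm * np.exp(-pco2_sigma * norm.ppf(undersaturated_fraction))
    pco2 = rng.lognormal(np.log(median), pco2_sigma, n_pco2_sites)
    sites = pd.DataFrame(
        {
            "site_id": [f"lentic-{i:04d}" for i in range(n_pco2_sites)],
            "region": rng.choice(REGIONS, n_pco2_sites),
            "kind": rng.choice(["lake", "reservoir"], n_pco2_sites),
            "pco2_uatm": pco2,
            "undersaturated": pco2 < atm,
        }
    )
    return bodies, sites


def gen_winds(n: int = 1000, mean: float = 2.2, sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """National wind-speed climatology sample (m/s at 10 m), truncated at zero."""
    rng = np.random.default_rng(seed)
    u = rng.normal(mean, sd, n)
    return np.abs(u)


def mean_lentic_k600(winds: np.ndarray) -> float:
    """Population-mean lentic k600 (cm/h) over a wind climatology."""
    return float(np.mean([k600_lentic(u).k600 for u in winds]))
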