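"""End-to-end orchestration: scenario tables in, audited report bundle out.

Stage order: dilute calibration -> pCO2 -> k600/k -> areal flux -> stratum
means -> stratified upscaling -> Monte Carlo -> carbon budget. Site-level
stages run when gauge tables are present; a bundle that already carries
stratum-mean fluxes (the scenario fixtures) enters at the upscaling stage.
Every stage's output is persisted as CSV next to a JSON report, and the log
records row counts, exclusions, seed and a config hash, so every number in
the report traces to a file on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import budget as budget_mod
from .carbonate import (
    DiluteCorrection,
    InvalidSampleError,
    WaterSample,
    apply_bias_factor,
    calibrate_dilute,
    equilibrium_constants,
    pco2_from_chemistry,
)
from .config import ScenarioConfig
from .flux import areal_flux, delta_pco2
from .gas_transfer import HydraulicState, k600_stream_energy, k600_stream_general
from .scenarios import ScenarioBundle, TERRESTRIAL_SINK
from .uncertainty import combine_independent, monte_carlo_efflux
from .upscale import (
    EffluxEstimate,
    efflux_lentic,
    efflux_streams,
    order_group_shares,
    per_order_efflux,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending records."""


def site_fluxes_from_gauges(
    chemistry: pd.DataFrame,
    hydraulics: pd.DataFrame,
    config: ScenarioConfig,
) -> pd.DataFrame:
    """Site-level areal fluxes from gauge chemistry + hydraulics.

    Applies the dilute calibration, solves pCO2, computes k600 by the
    configured method and converts to in-situ k, then evaluates the areal
    flux against the scenario's atmospheric reference. Sites with fewer than
    ``config.min_measurements`` observations are excluded; records whose
    chemistry is inconsistent are dropped with a logged reason.
    """
    if chemistry.empty or hydraulics.empty:
        raise PipelineError("stage pco2: empty input tables")
    counts = chemistry.groupby("site_id").size()
    keep = set(counts[counts >= config.min_measurements].index)
    excluded = len(counts) - len(keep)
    if excluded:
        logger.info("excluded %d sites below the %d-measurement screen", excluded, config.min_measurements)
    chem = chemistry[chemistry["site_id"].isin(keep)]
    hyd = hydraulics.set_index("site_id")
    correction = DiluteCorrection(f_org=config.dilute_f_org, delta_ph=config.dilute_delta_ph)

    rows, dropped = [], 0
    for r in chem.itertuples():
        try:
            sample = WaterSample(
                site_id=r.site_id,
                region=r.region,
                season=r.season,
                pH=r.pH,
                alkalinity=r.alkalinity_ueq_L,
                temp=r.temp_C,
            )
            sample = calibrate_dilute(sample, correction)
            pco2 = pco2_from_chemistry(sample)
        except InvalidSampleError as exc:
            logger.warning("dropped record: %s", exc)
            dropped += 1
            continue
        if config.bias_factor is not None:
            pco2 = apply_bias_factor(pco2, config.bias_factor)
        try:
            site = hyd.loc[r.site_id]
        except KeyError:
            dropped += 1
            continue
        h = HydraulicState(velocity=site["velocity_m_s"], slope=site["slope"])
        if config.k_method == "raymond" or h.energy_dissipation <= 0.0:
            tv = k600_stream_general(h, temp=r.temp_C)
        else:
            tv = k600_stream_energy(h, temp=r.temp_C)
        d = delta_pco2(pco2, config.atm_pco2)
        kh = equilibrium_constants(r.temp_C).KH
        rows.append(
            {
                "site_id": r.site_id,
                "region": r.region,
                "stratum": getattr(r, "order", np.nan),
                "season": r.season,
                "pco2_uatm": pco2,
                "k600_cm_h": tv.k600,
                "k_cm_h": tv.k,
                "F_mmol_m2_d": areal_flux(tv.k, kh, d),
            }
        )
    if dropped:
        logger.info("dropped %d records during pCO2/flux stages", dropped)
    if not rows:
        raise PipelineError("stage flux: no valid records survived")
    return pd.DataFrame(rows)


def stratum_means(site_fluxes: pd.DataFrame) -> pd.DataFrame:
    """Collapse site-level fluxes to (region, stratum, season) means."""
    g = site_fluxes.groupby(["region", "stratum", "season"])["F_mmol_m2_d"]
    out = g.agg(mean_F="mean", sd_F="std", n_sites="count").reset_index()
    out["sd_F"] = out["sd_F"].fillna(0.0)
    return out


def run_pipeline(config: ScenarioConfig, bundle: ScenarioBundle, outdir: str | Path) -> dict:
    """Upscale a scenario bundle to the national report; persist all stages.

    Returns the report dict (also written to ``outdir``/report.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in (
        ("stream_fluxes", bundle.stream_fluxes),
        ("lake_fluxes", bundle.lake_fluxes),
        ("reservoir_fluxes", bundle.reservoir_fluxes),
    ):
        if table.empty:
            raise PipelineError(f"stage validate: empty input table {name}")

    config_text = config.to_yaml()
    config_hash = hashlib.sha256(config_text.encode()).hexdigest()[:16]
    logger.info("run_pipeline period=%s seed=%d config=%s", config.period, config.seed, config_hash)
    (outdir / "config.yaml").write_text(config_text)
    bundle.write_csv(outdir / "inputs")

    ice = bundle.ice_free_days
    riv_nat, riv_reg, riv_cells = efflux_streams(bundle.stream_fluxes, bundle.stream_inventory, ice)
    lake_nat, lake_reg, lake_cells = efflux_lentic(bundle.lake_fluxes, bundle.lake_inventory, ice)
    res_nat, res_reg, res_cells = efflux_lentic(bundle.reservoir_fluxes, bundle.reservoir_inventory, ice)
    riv_cells.to_csv(outdir / "efflux_streams.csv", index=False)
    lake_cells.to_csv(outdir / "efflux_lakes.csv", index=False)
    res_cells.to_csv(outdir / "efflux_reservoirs.csv", index=False)

    seeds = np.random.SeedSequence(config.seed).spawn(3)
    mc = {
        "rivers": monte_carlo_efflux(
            bundle.stream_fluxes, bundle.stream_inventory, ice,
            n_iter=config.mc_iterations, seed=seeds[0], scope=(config.period, "national", "rivers"),
        ),
        "lakes": monte_carlo_efflux(
            bundle.lake_fluxes, bundle.lake_inventory, ice,
            n_iter=config.mc_iterations, seed=seeds[1], scope=(config.period, "national", "lakes"),
        ),
        "reservoirs": monte_carlo_efflux(
            bundle.reservoir_fluxes, bundle.reservoir_inventory, ice,
            n_iter=config.mc_iterations, seed=seeds[2], scope=(config.period, "national", "reservoirs"),
        ),
    }
    # central values are the deterministic stratified sums; Monte Carlo
    # supplies the spread (truncation at zero slightly shifts the MC mean)
    total = combine_independent(
        [
            EffluxEstimate(value=riv_nat.value, sd=mc["rivers"].sd),
            EffluxEstimate(value=lake_nat.value, sd=mc["lakes"].sd),
            EffluxEstimate(value=res_nat.value, sd=mc["reservoirs"].sd),
        ],
        scope=(config.period, "national", "all"),
    )

    shares = order_group_shares(per_order_efflux(riv_cells))
    lentic_total = lake_nat.value + res_nat.value
    soil = budget_mod.soil_co2_contribution(riv_nat.value, shares["headwater"], lentic_total)
    residual = budget_mod.residual_aquatic_flux(riv_nat.value + lentic_total, soil)
    sink_low, sink_high = TERRESTRIAL_SINK[config.period]
    offset = budget_mod.sink_offset(residual, sink_low, sink_high)

    rd, nd = config.region_decimals, config.national_decimals
    report = {
        "period": config.period,
        "seed": config.seed,
        "config_hash": config_hash,
        "regional_TgC_yr": {
            region: {
                "rivers": round(riv_reg[region].value, rd),
                "lakes": round(lake_reg[region].value, rd),
                "reservoirs": round(res_reg[region].value, rd),
            }
            for region in riv_reg
        },
        "national_TgC_yr": {
            "rivers": round(riv_nat.value, rd),
            "lakes": round(lake_nat.value, rd),
            "reservoirs": round(res_nat.value, rd),
            "total": round(total.value, nd),
            "total_sd": round(total.sd, nd),
            "total_ci5": round(total.ci5, nd),
            "total_ci95": round(total.ci95, nd),
        },
        "monte_carlo": {
            name: {"value": e.value, "sd": e.sd, "ci5": e.ci5, "ci95": e.ci95}
            for name, e in mc.items()
        },
        "order_group_shares": {k: round(v, 4) for k, v in shares.items()},
        "budget": {
            "soil_TgC_yr": round(soil, nd),
            "residual_TgC_yr": round(residual, nd),
            "sink_offset_pct": [round(offset[0]), round(offset[1])],
        },
        "stage_files": [
            "inputs/", "efflux_streams.csv", "efflux_lakes.csv", "efflux_reservoirs.csv",
        ],
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
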