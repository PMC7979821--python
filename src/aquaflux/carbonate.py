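"""Freshwater carbonate speciation: pCO2 from pH, alkalinity and temperature.

Surface-water pCO2 is computed from routine gauge measurements (pH on the NBS
scale, total titration alkalinity in ueq/L, water temperature) under the dilute
freshwater assumption: zero salinity, unit activity coefficients, and titration
alkalinity interpreted as carbonate alkalinity

    CA = [HCO3-] + 2[CO32-] + [OH-] - [H+]   (eq/L).

Given [H+] = 10^-pH, the bicarbonate concentration follows from CA, then
CO2* = [HCO3-][H+]/K1 and pCO2 = CO2*/KH.

Dissociation constants K1, K2 and Henry's constant KH use the zero-salinity
temperature fits of Plummer & Busenberg (1982); the water ion product Kw uses
Millero (1995) at S=0. A Poynting factor adjusts KH for station pressure
(negligible below ~3000 m elevation but kept for completeness on high-altitude
plateau gauges).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

REGIONS = (
    "GreaterPearl",
    "Yangtze",
    "HuangHuaiHai",
    "NEChina",
    "NWChina",
    "TibetanPlateau",
)

SEASONS = ("dry", "wet")

#: gas constant in cm3 atm / (mol K), for the Poynting pressure factor
_R_CM3_ATM = 82.0574
#: partial molar volume of dissolved CO2, cm3/mol
_V_CO2_CM3 = 32.3

TEMP_MIN_C = -0.5
TEMP_MAX_C = 45.0


class DomainError(ValueError):
    """An input fell outside the physically admissible range."""


class InvalidSampleError(ValueError):
    """A chemistry record is internally inconsistent (e.g. pH vs alkalinity)."""


@dataclass(frozen=True)
class CarbonateConstants:
    """Zero-salinity carbonate system constants at a given temperature.

    K1, K2 in mol/L, Kw in mol^2/L^2, KH in mol/(L atm).
    """

    K1: float
    K2: float
    Kw: float
    KH: float
    temp: float


@dataclass
class WaterSample:
    """One gauge water-chemistry observation.

    alkalinity is total titration alkalinity in ueq/L; pressure is station
    barometric pressure in atm (1.0 at sea level).
    """

    site_id: str
    region: str
    season: str
    pH: float
    alkalinity: float
    temp: float
    pressure: float = 1.0
    calibrated: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.pH < 14.0):
            raise DomainError(f"pH out of range (0, 14): {self.pH}")
        if self.alkalinity < 0:
            raise DomainError(f"alkalinity must be >= 0 ueq/L: {self.alkalinity}")
        if not (TEMP_MIN_C <= self.temp <= TEMP_MAX_C):
            raise DomainError(f"temp out of range [{TEMP_MIN_C}, {TEMP_MAX_C}] C: {self.temp}")
        if self.pressure <= 0:
            raise DomainError(f"pressure must be > 0 atm: {self.pressure}")


def equilibrium_constants(temp: float, pressure: float = 1.0) -> CarbonateConstants:
    """Freshwater carbonate constants at ``temp`` (deg C) and ``pressure`` (atm).

    Plummer & Busenberg (1982) log10 fits for K1, K2 and KH (their K_CO2, i.e.
    Henry's constant for CO2(g) <-> CO2*(aq)); Millero (1995) ln fit for Kw at
    S=0. KH carries a Poynting correction exp(v_CO2 (1-P) / RT).
    """
    if not (TEMP_MIN_C <= temp <= TEMP_MAX_C):
        raise DomainError(f"temp out of range [{TEMP_MIN_C}, {TEMP_MAX_C}] C: {temp}")
    if pressure <= 0:
        raise DomainError(f"pressure must be > 0 atm: {pressure}")

    T = temp + 273.15
    log10_T = math.log10(T)

    log10_K1 = -356.3094 - 0.06091964 * T + 21834.37 / T + 126.8339 * log10_T - 1684915.0 / T**2
    log10_K2 = -107.8871 - 0.03252849 * T + 5151.79 / T + 38.92561 * log10_T - 563713.9 / T**2
    log10_KH = 108.3865 + 0.01985076 * T - 6919.53 / T - 40.45154 * log10_T + 669365.0 / T**2
    ln_Kw = 148.9802 - 13847.26 / T - 23.6521 * math.log(T)

    poynting = math.exp(_V_CO2_CM3 * (1.0 - pressure) / (_R_CM3_ATM * T))
    return CarbonateConstants(
        K1=10.0**log10_K1,
        K2=10.0**log10_K2,
        Kw=math.exp(ln_Kw),
        KH=10.0**log10_KH * poynting,
        temp=temp,
    )


def pco2_from_chemistry(sample: WaterSample) -> float:
    """pCO2 (uatm) of a gauge sample from pH, alkalinity and temperature.

    Raises InvalidSampleError when the solved [HCO3-] is non-positive, i.e. the
    reported alkalinity cannot be carbonate alkalinity at the reported pH.
    """
    c = equilibrium_constants(sample.temp, sample.pressure)
    h = 10.0 ** (-sample.pH)
    ca = sample.alkalinity * 1e-6  # ueq/L -> eq/L
    oh = c.Kw / h
    hco3 = (ca - oh + h) / (1.0 + 2.0 * c.K2 / h)
    if hco3 <= 0.0:
        raise InvalidSampleError(
            f"site {sample.site_id}: alkalinity {sample.alkalinity} ueq/L inconsistent "
            f"with pH {sample.pH} (non-positive [HCO3-])"
        )
    co2_star = hco3 * h / c.K1
    return co2_star / c.KH * 1e6


def alkalinity_from_pco2(pH: float, pco2: float, temp: float, pressure: float = 1.0) -> float:
    """Carbonate alkalinity (ueq/L) implied by a (pH, pCO2) pair; round-trip check."""
    c = equilibrium_constants(temp, pressure)
    h = 10.0 ** (-pH)
    co2_star = c.KH * pco2 * 1e-6
    hco3 = c.K1 * co2_star / h
    co3 = c.K2 * hco3 / h
    return (hco3 + 2.0 * co3 + c.Kw / h - h) * 1e6


def ph_from_pco2(
    pco2: np.ndarray | float,
    alkalinity: np.ndarray | float,
    temp: np.ndarray | float,
    pressure: float = 1.0,
) -> np.ndarray:
    """Invert the speciation: pH such that (pH, alkalinity, temp) gives ``pco2``.

    Solves the cubic in h = [H+]

        h^3 + CA h^2 - (K1 CO2* + Kw) h - 2 K1 K2 CO2* = 0

    by vectorized Newton iteration from h0 = K1 CO2*/CA. Used by the synthetic
    gauge generator so that generated chemistry is exactly consistent with the
    target pCO2 population.
    """
    pco2 = np.asarray(pco2, dtype=float)
    alk = np.asarray(alkalinity, dtype=float) * 1e-6
    temp = np.broadcast_to(np.asarray(temp, dtype=float), np.broadcast_shapes(pco2.shape, alk.shape, np.shape(temp))).astype(float)
    pco2, alk = np.broadcast_arrays(pco2, alk)

    T = temp + 273.15
    log10_T = np.log10(T)
    K1 = 10.0 ** (-356.3094 - 0.06091964 * T + 21834.37 / T + 126.8339 * log10_T - 1684915.0 / T**2)
    K2 = 10.0 ** (-107.8871 - 0.03252849 * T + 5151.79 / T + 38.92561 * log10_T - 563713.9 / T**2)
    KH = 10.0 ** (108.3865 + 0.01985076 * T - 6919.53 / T - 40.45154 * log10_T + 669365.0 / T**2)
    KH = KH * np.exp(_V_CO2_CM3 * (1.0 - pressure) / (_R_CM3_ATM * T))
    Kw = np.exp(148.9802 - 13847.26 / T - 23.6521 * np.log(T))

    co2 = KH * pco2 * 1e-6
    b = alk
    c1 = K1 * co2 + Kw
    d = 2.0 * K1 * K2 * co2

    h = np.maximum(K1 * co2 / np.maximum(alk, 1e-12), 1e-12)
    for _ in range(60):
        f = h**3 + b * h**2 - c1 * h - d
        fp = 3.0 * h**2 + 2.0 * b * h - c1
        step = f / fp
        h = np.clip(h - step, 1e-14, 1e-2)
    resid = h**3 + b * h**2 - c1 * h - d
    scale = np.maximum(np.abs(c1 * h), 1e-30)
    if not np.all(np.abs(resid) / scale < 1e-8):
        raise RuntimeError("pH inversion failed to converge for some samples")
    return -np.log10(h)


@dataclass(frozen=True)
class DiluteCorrection:
    """Parameters of the low-alkalinity (dilute water) calibration.

    Gauge pCO2 computed from pH/alkalinity is biased high in dilute, organic-rich
    waters, where part of the titration alkalinity is organic. The cited
    correction's functional form is not public, so the hook is pluggable: the
    default subtracts a fraction ``f_org`` of the alkalinity (organic share)
    and shifts pH by ``delta_ph``. With f_org=0 and delta_ph=0 it is the
    identity; these are the defaults, i.e. the correction is a stand-in the
    user must parameterize deliberately.
    """

    f_org: float = 0.0
    delta_ph: float = 0.0
    threshold: float = 1000.0  # ueq/L; records at or above are never touched


def calibrate_dilute(sample: WaterSample, params: DiluteCorrection = DiluteCorrection()) -> WaterSample:
    """Apply the dilute-water calibration to samples below the alkalinity threshold.

    Identity for alkalinity >= threshold (default 1000 ueq/L). Corrected
    samples carry ``calibrated=True``; a correction that would drive
    alkalinity negative clamps it to zero (and still flags the record).
    """
    if sample.alkalinity >= params.threshold:
        return sample
    new_alk = sample.alkalinity * (1.0 - params.f_org)
    if new_alk < 0.0:
        logger.warning("site %s: dilute correction clamped alkalinity to 0", sample.site_id)
        new_alk = 0.0
    new_ph = sample.pH + params.delta_ph
    if params.f_org == 0.0 and params.delta_ph == 0.0:
        return sample
    return replace(sample, alkalinity=new_alk, pH=new_ph, calibrated=True)


def apply_bias_factor(pco2: float, factor: float = 1.09) -> float:
    """Divide a computed pCO2 by a validation bias factor (default 9% high bias).

    Off by default in the pipeline; exposed for sensitivity runs.
    """
    if factor <= 0:
        raise DomainError(f"bias factor must be > 0: {factor}")
    return pco2 / factor


def pressure_from_elevation(elevation_m: float) -> float:
    """Station pressure (atm) from elevation via the standard barometric formula."""
    return (1.0 - 2.25577e-5 * elevation_m) ** 5.25588
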