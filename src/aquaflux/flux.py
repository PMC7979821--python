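"""Areal CO2 flux across the water-air interface.

F_CO2 = k * kH * dpCO2, with k in cm/h, kH in mol/(L atm) and dpCO2 in uatm
(water minus air). The unit chain: k * 0.24 converts cm/h to m/d; kH * dpCO2
is umol/L = mmol/m3; the product is mmol m-2 d-1. Positive flux is evasion to
the atmosphere, negative is invasion into the water.
"""

from __future__ import annotations

from dataclasses import dataclass

from .carbonate import DomainError

#: cm/h -> m/d
CM_PER_H_TO_M_PER_D = 0.24


@dataclass(frozen=True)
class FluxRecord:
    """One areal flux with its drivers; source distinguishes direct chamber or
    eddy measurements (used as-is) from fluxes computed via k and dpCO2."""

    F_CO2: float  # mmol m-2 d-1
    k: float  # cm/h
    kH: float  # mol/(L atm)
    delta_pCO2: float  # uatm
    source: str = "computed"


def delta_pco2(water_pco2: float, atm_pco2: float) -> float:
    """Water-air pCO2 gradient (uatm); positive drives evasion."""
    if water_pco2 < 0 or atm_pco2 < 0:
        raise DomainError("pCO2 values must be >= 0")
    return water_pco2 - atm_pco2


def areal_flux(k: float, kH: float, delta_pCO2: float) -> float:
    """Areal CO2 flux in mmol m-2 d-1 from Fick's law across the interface."""
    if k <= 0:
        raise DomainError(f"k must be > 0 cm/h: {k}")
    if kH <= 0:
        raise DomainError(f"kH must be > 0 mol/(L atm): {kH}")
    return k * CM_PER_H_TO_M_PER_D * kH * delta_pCO2


def flux_record(k: float, kH: float, water_pco2: float, atm_pco2: float) -> FluxRecord:
    d = delta_pco2(water_pco2, atm_pco2)
    return FluxRecord(F_CO2=areal_flux(k, kH, d), k=k, kH=kH, delta_pCO2=d)
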