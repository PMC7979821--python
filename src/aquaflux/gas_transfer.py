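"""Gas transfer velocities (k600) for flowing and standing waters.

Streams and rivers: either a general hydraulic scaling (k600 linear in the
velocity-slope product V*S) or a two-regime energy-dissipation scaling that
distinguishes low-energy from high-energy channels at eD = g*S*V = 0.02 m2/s3.
Lakes and reservoirs: piecewise wind models with a breakpoint at U10 = 3.7 m/s.

All coefficients live in an editable registry with citation strings, so an
alternative parameterization is a config change, not a code change. k600 is
converted to in-situ k through the Schmidt number of CO2 in fresh water
(Wanninkhof 2014 polynomial), with exponent -1/2 for turbulent/wind-sheared
surfaces and -2/3 for smooth (calm lentic) surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import yaml

from .carbonate import DomainError

G = 9.80665  # m/s2
M_PER_DAY_TO_CM_PER_H = 100.0 / 24.0

#: energy-dissipation regime breakpoint, m2/s3 (boundary value -> high regime)
ED_BREAKPOINT = 0.02
#: wind-speed regime breakpoint at 10 m, m/s (boundary value -> high regime)
WIND_BREAKPOINT = 3.7


@dataclass(frozen=True)
class HydraulicState:
    """Reach-scale hydraulics at a gauge: velocity (m/s), slope (m/m), depth,
    width (m), discharge (m3/s)."""

    velocity: float
    slope: float
    depth: float = float("nan")
    width: float = float("nan")
    discharge: float = float("nan")

    def __post_init__(self) -> None:
        if self.velocity < 0 or self.slope < 0:
            raise DomainError("velocity and slope must be >= 0")
        if self.slope >= 1:
            raise DomainError(f"slope must be < 1 m/m: {self.slope}")

    @property
    def energy_dissipation(self) -> float:
        """eD = g * S * V, m2/s3."""
        return G * self.slope * self.velocity


@dataclass(frozen=True)
class TransferVelocity:
    """k600 and the in-situ k, both cm/h, with the method that produced them."""

    k600: float
    k: float
    method: str


@dataclass(frozen=True)
class K600Model:
    """One registry entry: coefficients plus the literature source they came from."""

    coeffs: tuple[float, ...]
    units: str
    citation: str


DEFAULT_REGISTRY: dict[str, K600Model] = {
    # k600 [m/d] = a * (V*S) + b
    "raymond": K600Model(
        coeffs=(2841.6, 2.02),
        units="m d-1",
        citation="Raymond et al. (2012) hydraulic scaling, k600 = 2841.6 VS + 2.02",
    ),
    # ln k600 [m/d] = a * ln eD + b, low-energy regime (eD < 0.02 m2/s3)
    "ulseth_low": K600Model(
        coeffs=(0.35, 3.10),
        units="ln(m d-1)",
        citation="Ulseth et al. (2019) low-energy streams, ln k600 = 0.35 ln eD + 3.10",
    ),
    # ln k600 [m/d] = a * ln eD + b, high-energy regime (eD >= 0.02 m2/s3)
    "ulseth_high": K600Model(
        coeffs=(1.18, 6.43),
        units="ln(m d-1)",
        citation="Ulseth et al. (2019) high-energy streams, ln k600 = 1.18 ln eD + 6.43",
    ),
    # k600 [cm/h] = a + b * U10^c, low-wind regime (U10 < 3.7 m/s)
    "wind_low": K600Model(
        coeffs=(2.07, 0.215, 1.7),
        units="cm h-1",
        citation="Cole & Caraco (1998), k600 = 2.07 + 0.215 U10^1.7",
    ),
    # k600 [cm/h] = a + b * U10^c, high-wind regime (U10 >= 3.7 m/s)
    "wind_high": K600Model(
        coeffs=(0.168, 0.228, 2.2),
        units="cm h-1",
        citation="Crusius & Wanninkhof (2003) power model, k600 = 0.168 + 0.228 U10^2.2",
    ),
}


def registry_to_yaml(registry: Mapping[str, K600Model] | None = None) -> str:
    registry = DEFAULT_REGISTRY if registry is None else registry
    return yaml.safe_dump(
        {name: {**asdict(m), "coeffs": list(m.coeffs)} for name, m in registry.items()},
        sort_keys=True,
    )


def registry_from_yaml(text: str) -> dict[str, K600Model]:
    raw = yaml.safe_load(text)
    return {
        name: K600Model(coeffs=tuple(d["coeffs"]), units=d["units"], citation=d["citation"])
        for name, d in raw.items()
    }


def schmidt_number(temp: float) -> float:
    """Schmidt number of CO2 in fresh water at ``temp`` deg C (Wanninkhof 2014).

    Sc(20 C) = 600 by construction of the normalization.
    """
    if not (0.0 <= temp <= 40.0):
        raise DomainError(f"temp out of range [0, 40] C for Schmidt polynomial: {temp}")
    t = temp
    return 1923.6 - 125.06 * t + 4.3773 * t**2 - 0.085681 * t**3 + 0.00070284 * t**4


def k_from_k600(k600: float, temp: float, exponent: float = -0.5) -> float:
    """Convert k600 (cm/h) to in-situ k at ``temp`` via (Sc/600)^exponent."""
    if k600 <= 0:
        raise DomainError(f"k600 must be > 0: {k600}")
    return k600 * (schmidt_number(temp) / 600.0) ** exponent


def k600_stream_general(
    h: HydraulicState,
    coeffs: K600Model | None = None,
    temp: float = 20.0,
) -> TransferVelocity:
    """General hydraulic k600: linear in V*S, intercept-only at zero slope."""
    m = coeffs or DEFAULT_REGISTRY["raymond"]
    a, b = m.coeffs
    k600 = (a * h.velocity * h.slope + b) * M_PER_DAY_TO_CM_PER_H
    return TransferVelocity(k600=k600, k=k_from_k600(k600, temp, -0.5), method="raymond")


def k600_stream_energy(
    h: HydraulicState,
    breakpoint: float = ED_BREAKPOINT,
    coeffs_low: K600Model | None = None,
    coeffs_high: K600Model | None = None,
    temp: float = 20.0,
) -> TransferVelocity:
    """Two-regime energy-dissipation k600; eD at the breakpoint is high-energy.

    The two log-log fits are deliberately not continuous at the breakpoint;
    zero eD (flat or stagnant reaches) is undefined here and must be routed to
    the general relationship by the caller.
    """
    import math

    eD = h.energy_dissipation
    if eD <= 0.0:
        raise DomainError("energy dissipation is zero; use the general hydraulic model")
    if eD >= breakpoint:
        m = coeffs_high or DEFAULT_REGISTRY["ulseth_high"]
        method = "ulseth_high"
    else:
        m = coeffs_low or DEFAULT_REGISTRY["ulseth_low"]
        method = "ulseth_low"
    a, b = m.coeffs
    k600 = math.exp(a * math.log(eD) + b) * M_PER_DAY_TO_CM_PER_H
    return TransferVelocity(k600=k600, k=k_from_k600(k600, temp, -0.5), method=method)


def k600_lentic(
    U10: float,
    breakpoint: float = WIND_BREAKPOINT,
    coeffs_low: K600Model | None = None,
    coeffs_high: K600Model | None = None,
    temp: float = 20.0,
) -> TransferVelocity:
    """Piecewise wind-based k600 for lakes and reservoirs.

    Below the breakpoint the smooth-surface (-2/3) Schmidt exponent applies,
    at or above it the sheared-surface (-1/2) exponent.
    """
    if U10 < 0:
        raise DomainError(f"wind speed must be >= 0: {U10}")
    if U10 >= breakpoint:
        m = coeffs_high or DEFAULT_REGISTRY["wind_high"]
        method, exponent = "wind_high", -0.5
    else:
        m = coeffs_low or DEFAULT_REGISTRY["wind_low"]
        method, exponent = "wind_low", -2.0 / 3.0
    a, b, c = m.coeffs
    k600 = a + b * U10**c
    return TransferVelocity(k600=k600, k=k_from_k600(k600, temp, exponent), method=method)
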