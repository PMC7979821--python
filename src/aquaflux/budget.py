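"""Carbon-budget partitioning of inland-water CO2 evasion.

The evaded CO2 is split into a terrestrially respired component (soil CO2
exported laterally into the network) and a residual produced within the
aquatic domain (mostly mineralization of terrestrial organic matter). The
split assumes soil respiration supplies 90% of headwater-stream evasion and
20% of evasion from higher-order streams, lakes and reservoirs. The residual
is the part not already counted by biomass-based terrestrial sink estimates,
so its ratio to the sink bounds gives the sink offset. Efflux change between
periods is decomposed into areal-flux and surface-area contributions with an
exactly additive mean-anchored two-factor split.
"""

from __future__ import annotations

from dataclasses import dataclass

from .carbonate import DomainError


@dataclass(frozen=True)
class PartitionParams:
    """Soil-respiration shares of evasion and the terrestrial sink bounds."""

    f_headwater: float = 0.90
    f_other: float = 0.20
    sink_low: float | None = None  # Tg C yr-1
    sink_high: float | None = None

    def __post_init__(self) -> None:
        for f in (self.f_headwater, self.f_other):
            if not (0.0 <= f <= 1.0):
                raise DomainError(f"partition fractions must be in [0, 1]: {f}")


def soil_co2_contribution(
    riverine_total: float,
    headwater_share: float,
    lentic_total: float,
    params: PartitionParams = PartitionParams(),
) -> float:
    """Soil-respired fraction of total evasion (Tg C yr-1).

    f_head applies to the headwater share of riverine evasion; f_other to the
    remaining riverine evasion and to all lentic evasion.
    """
    if not (0.0 <= headwater_share <= 1.0):
        raise DomainError(f"headwater share must be in [0, 1]: {headwater_share}")
    head = headwater_share * riverine_total
    other = (1.0 - headwater_share) * riverine_total + lentic_total
    return params.f_headwater * head + params.f_other * other


def residual_aquatic_flux(total: float, soil: float) -> float:
    """Evasion not attributable to soil respiration: total - soil."""
    if total < soil:
        raise DomainError(f"soil contribution {soil} exceeds total {total}")
    return total - soil


def sink_offset(residual: float, sink_low: float, sink_high: float) -> tuple[float, float]:
    """Percent of the terrestrial carbon sink offset by the residual evasion.

    Returns (low, high) percentages: residual over the high and low sink
    bounds respectively.
    """
    if sink_low <= 0 or sink_high <= 0:
        raise DomainError("sink bounds must be > 0")
    if residual < 0:
        raise DomainError("residual must be >= 0")
    return 100.0 * residual / sink_high, 100.0 * residual / sink_low


@dataclass(frozen=True)
class ChangeDecomposition:
    """Additive split of an efflux change into rate and area contributions."""

    delta_efflux: float
    from_flux: float  # contribution of the areal-flux change
    from_area: float  # contribution of the surface-area change
    share_flux_pct: float | None  # None when delta_efflux == 0
    share_area_pct: float | None


def change_decomposition(F1: float, SA1: float, F2: float, SA2: float) -> ChangeDecomposition:
    """Mean-anchored two-factor decomposition of E = F * SA between periods.

    dE = dF * mean(SA) + dSA * mean(F) holds exactly, so the two percentage
    shares sum to 100 (one may be negative when the drivers oppose). Shares
    are undefined (None) when the efflux did not change.
    """
    if F1 <= 0 or SA1 <= 0:
        raise DomainError("baseline flux and area must be > 0")
    dF, dSA = F2 - F1, SA2 - SA1
    mean_F, mean_SA = (F1 + F2) / 2.0, (SA1 + SA2) / 2.0
    from_flux = dF * mean_SA
    from_area = dSA * mean_F
    dE = from_flux + from_area
    if dE == 0.0:
        return ChangeDecomposition(0.0, from_flux, from_area, None, None)
    return ChangeDecomposition(
        delta_efflux=dE,
        from_flux=from_flux,
        from_area=from_area,
        share_flux_pct=100.0 * from_flux / dE,
        share_area_pct=100.0 * from_area / dE,
    )


def percent_change(v1: float, v2: float) -> float:
    """Relative change 100 * (v2 - v1) / v1."""
    if v1 == 0:
        raise DomainError("baseline value must be nonzero")
    return 100.0 * (v2 - v1) / v1
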