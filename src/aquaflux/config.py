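"""Scenario configuration: one YAML-serializable object drives a whole run."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .carbonate import REGIONS
from .scenarios import ATM_PCO2, DEFAULT_ICE_FREE_DAYS, PERIODS


@dataclass
class ScenarioConfig:
    """Everything a reproducible end-to-end run depends on.

    ``k_method`` selects the stream gas-transfer scaling ("raymond" hydraulic
    or "ulseth" energy-dissipation; reported runs use the hydraulic one).
    ``bias_factor`` optionally divides computed pCO2 by a validation bias
    (e.g. 1.09); None leaves it off. Rounding rules mirror report style:
    one decimal for regional Tg values, integers nationally.
    """

    period: str = "2010s"
    atm_pco2: float | None = None  # uatm; None -> period default
    season_months: dict = field(
        default_factory=lambda: {"dry": [11, 12, 1, 2, 3, 4], "wet": [5, 6, 7, 8, 9, 10]}
    )
    ice_free_days: dict = field(default_factory=lambda: {r: dict(d) for r, d in DEFAULT_ICE_FREE_DAYS.items()})
    k_method: str = "raymond"
    wind_models: tuple = ("wind_low", "wind_high")
    dilute_f_org: float = 0.0
    dilute_delta_ph: float = 0.0
    bias_factor: float | None = None
    min_measurements: int = 25
    mc_iterations: int = 10_000
    seed: int = 0
    region_decimals: int = 1
    national_decimals: int = 0

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}")
        if self.mc_iterations < 1:
            raise ValueError("mc_iterations must be >= 1")
        unknown = set(self.ice_free_days) - set(REGIONS)
        if unknown:
            raise ValueError(f"ice_free_days references undefined regions: {sorted(unknown)}")
        if self.atm_pco2 is None:
            self.atm_pco2 = ATM_PCO2[self.period]
        self.wind_models = tuple(self.wind_models)

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["wind_models"] = list(self.wind_models)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ScenarioConfig":
        text = Path(source).read_text() if isinstance(source, Path) or "\n" not in str(source) else str(source)
        return cls(**yaml.safe_load(text))
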