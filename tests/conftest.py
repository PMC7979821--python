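import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from aquaflux.config import ScenarioConfig
from aquaflux.pipeline import site_fluxes_from_gauges
from aquaflux.scenarios import gen_scenario
from aquaflux.synthetic import gen_gauges


@pytest.fixture(scope="session")
def bundle_1980s():
    return gen_scenario("1980s", seed=0)


@pytest.fixture(scope="session")
def bundle_2010s():
    return gen_scenario("2010s", seed=0)


@pytest.fixture(scope="session")
def gauge_tables():
    """Default 2010s synthetic gauge chemistry + hydraulics (fixed seed)."""
    return gen_gauges(period="2010s", seed=1)


@pytest.fixture(scope="session")
def gauge_site_fluxes(gauge_tables):
    """Forward pipeline (calibrate -> pCO2 -> k -> flux) over the gauge set."""
    chem, hyd = gauge_tables
    return site_fluxes_from_gauges(chem, hyd, ScenarioConfig(period="2010s"))
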