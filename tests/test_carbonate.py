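import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquaflux.carbonate import (
    DiluteCorrection,
    DomainError,
    InvalidSampleError,
    WaterSample,
    alkalinity_from_pco2,
    apply_bias_factor,
    calibrate_dilute,
    equilibrium_constants,
    pco2_from_chemistry,
    ph_from_pco2,
    pressure_from_elevation,
)
from oracles import oracle_pco2


def sample(pH=7.0, alk=1000.0, temp=25.0, **kw):
    return WaterSample("s1", "Yangtze", "dry", pH, alk, temp, **kw)


class TestEquilibriumConstants:
    def test_reference_values_at_25C(self):
        c = equilibrium_constants(25.0)
        assert -math.log10(c.K1) == pytest.approx(6.35, abs=0.02)
        assert c.KH == pytest.approx(0.034, rel=0.05)
        assert c.K1 > c.K2 > 0
        assert c.Kw > 0

    def test_solubility_decreases_with_temperature(self):
        temps = np.arange(0.0, 41.0, 5.0)
        khs = [equilibrium_constants(t).KH for t in temps]
        assert all(a > b for a, b in zip(khs, khs[1:]))

    def test_out_of_range_temperature_names_field(self):
        with pytest.raises(DomainError, match="temp"):
            equilibrium_constants(60.0)
        with pytest.raises(DomainError, match="pressure"):
            equilibrium_constants(25.0, pressure=0.0)

    def test_altitude_pressure_correction_is_small(self):
        p = pressure_from_elevation(4500.0)  # plateau gauge
        assert 0.5 < p < 0.65
        kh_alt = equilibrium_constants(25.0, pressure=p).KH
        kh_sea = equilibrium_constants(25.0).KH
        assert kh_alt == pytest.approx(kh_sea, rel=0.01)
        assert kh_alt > kh_sea


class TestPco2FromChemistry:
    def test_hand_speciation_example(self):
        # pH 7, CA ~1e-3 eq/L: [HCO3-]~1e-3, CO2* = 1e-3*1e-7/10^-6.35, /KH
        assert pco2_from_chemistry(sample()) == pytest.approx(6.6e3, rel=0.10)

    def test_high_ph_water_is_undersaturated(self):
        assert pco2_from_chemistry(sample(pH=11.0, alk=2000.0)) < 400.0

    def test_inconsistent_chemistry_rejected(self):
        with pytest.raises(InvalidSampleError, match="inconsistent"):
            pco2_from_chemistry(sample(pH=11.5, alk=5.0))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        pH=st.floats(5.5, 9.5),
        alk=st.floats(100.0, 5000.0),
        temp=st.floats(5.0, 30.0),
    )
    def test_monotone_in_ph_and_alkalinity(self, pH, alk, temp):
        p0 = pco2_from_chemistry(sample(pH=pH, alk=alk, temp=temp))
        p_higher_ph = pco2_from_chemistry(sample(pH=pH + 0.1, alk=alk, temp=temp))
        p_higher_alk = pco2_from_chemistry(sample(pH=pH, alk=alk * 1.1, temp=temp))
        assert p_higher_ph < p0
        assert p_higher_alk > p0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        pH=st.floats(6.0, 9.0),
        alk=st.floats(200.0, 4000.0),
        temp=st.floats(5.0, 30.0),
    )
    def test_alkalinity_round_trip(self, pH, alk, temp):
        p = pco2_from_chemistry(sample(pH=pH, alk=alk, temp=temp))
        assert alkalinity_from_pco2(pH, p, temp) == pytest.approx(alk, rel=1e-3)

    def test_agreement_with_independent_oracle(self):
        for pH in np.arange(6.0, 9.01, 0.5):
            for temp in (5.0, 15.0, 25.0, 30.0):
                for alk in (300.0, 1000.0, 3000.0):
                    try:
                        ours = pco2_from_chemistry(sample(pH=pH, alk=alk, temp=temp))
                        ref = oracle_pco2(pH, alk, temp)
                    except (InvalidSampleError, ValueError):
                        continue
                    assert ours == pytest.approx(ref, rel=0.05)

    def test_ph_inversion_consistent_with_forward_solve(self):
        pco2 = np.array([500.0, 2798.0, 12000.0])
        alk = np.array([800.0, 1800.0, 3000.0])
        ph = ph_from_pco2(pco2, alk, 20.0)
        for i in range(3):
            back = pco2_from_chemistry(sample(pH=float(ph[i]), alk=float(alk[i]), temp=20.0))
            assert back == pytest.approx(pco2[i], rel=1e-6)


class TestDiluteCalibration:
    def test_identity_above_threshold(self):
        s = sample(alk=1500.0)
        assert calibrate_dilute(s, DiluteCorrection(f_org=0.2, delta_ph=-0.1)) is s

    def test_identity_with_neutral_parameters(self):
        s = sample(alk=500.0)
        assert calibrate_dilute(s, DiluteCorrection()) is s

    def test_default_rule_arithmetic(self):
        out = calibrate_dilute(sample(alk=500.0), DiluteCorrection(f_org=0.2))
        assert out.alkalinity == pytest.approx(400.0)
        assert out.calibrated

    def test_bias_factor(self):
        assert apply_bias_factor(1090.0, 1.09) == pytest.approx(1000.0)
        assert apply_bias_factor(123.4, 1.0) == 123.4
        assert apply_bias_factor(2798.0, 1.09) == pytest.approx(2567.0, abs=0.1)


def test_invalid_sample_fields_rejected():
    with pytest.raises(DomainError):
        sample(pH=15.0)
    with pytest.raises(DomainError):
        sample(alk=-1.0)
    with pytest.raises(DomainError):
        sample(temp=50.0)
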