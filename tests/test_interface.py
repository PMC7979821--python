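import json
from pathlib import Path

import pandas as pd
import pytest

from aquaflux.config import ScenarioConfig
from aquaflux.io import (
    read_chemistry_csv,
    read_hydraulics_csv,
    read_ice_free_csv,
    read_inventory_csv,
    read_network_csv,
)
from aquaflux.pipeline import PipelineError, run_pipeline, site_fluxes_from_gauges
from aquaflux.scenarios import gen_scenario


class TestConfig:
    def test_yaml_round_trip_equality(self, tmp_path):
        cfg = ScenarioConfig(period="1980s", seed=42, mc_iterations=500, dilute_f_org=0.1)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert ScenarioConfig.from_yaml(path) == cfg

    def test_period_default_atmosphere(self):
        assert ScenarioConfig(period="1980s").atm_pco2 == 340.0
        assert ScenarioConfig(period="2010s").atm_pco2 == 400.0

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(period="1880s")
        with pytest.raises(ValueError):
            ScenarioConfig(mc_iterations=0)
        with pytest.raises(ValueError):
            ScenarioConfig(ice_free_days={"Atlantis": {"dry": 1}})


class TestPipeline:
    def test_first_period_report_totals(self, tmp_path, bundle_1980s):
        cfg = ScenarioConfig(period="1980s", seed=3, mc_iterations=2000)
        report = run_pipeline(cfg, bundle_1980s, tmp_path / "out")
        nat = report["national_TgC_yr"]
        assert nat["total"] == 138.0
        assert nat["rivers"] == 128.6

    def test_empty_inputs_abort_without_partial_outputs(self, tmp_path, bundle_1980s):
        import dataclasses

        broken = dataclasses.replace(bundle_1980s, stream_fluxes=pd.DataFrame())
        out = tmp_path / "broken"
        with pytest.raises(PipelineError, match="stream_fluxes"):
            run_pipeline(ScenarioConfig(period="1980s"), broken, out)
        assert not any(out.glob("*"))

    def test_runs_are_byte_identical_under_fixed_seed(self, tmp_path, bundle_2010s):
        cfg = ScenarioConfig(period="2010s", seed=9, mc_iterations=1000)
        run_pipeline(cfg, bundle_2010s, tmp_path / "a")
        run_pipeline(cfg, bundle_2010s, tmp_path / "b")
        a = (tmp_path / "a" / "report.json").read_bytes()
        b = (tmp_path / "b" / "report.json").read_bytes()
        assert a == b

    def test_report_numbers_trace_to_persisted_stages(self, tmp_path, bundle_2010s):
        cfg = ScenarioConfig(period="2010s", seed=1, mc_iterations=500)
        out = tmp_path / "audit"
        report = run_pipeline(cfg, bundle_2010s, out)
        for name in report["stage_files"]:
            assert (out / name).exists()
        rivers = pd.read_csv(out / "efflux_streams.csv")["efflux_TgC"].sum()
        assert round(rivers, 1) == report["national_TgC_yr"]["rivers"]
        assert (out / "config.yaml").exists()

    def test_site_stage_respects_measurement_screen(self, gauge_tables):
        chem, hyd = gauge_tables
        thin = chem.groupby("site_id").head(10)  # every site below the screen
        with pytest.raises(PipelineError):
            site_fluxes_from_gauges(thin, hyd, ScenarioConfig(period="2010s"))


class TestReaders:
    def test_chemistry_reader_skips_malformed_rows(self, tmp_path):
        p = tmp_path / "chem.csv"
        p.write_text(
            "site_id,region,pH,alkalinity_ueq_L,temp_C\n"
            "a,Yangtze,7.1,1500,20\n"
            "b,Yangtze,not_a_number,1500,20\n"
            "c,Yangtze,7.2,-5,20\n"
            "d,Yangtze,7.3,900,99\n"
        )
        df = read_chemistry_csv(p)
        assert df["site_id"].tolist() == ["a"]

    def test_chemistry_reader_requires_headers(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("site_id,pH\na,7\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_chemistry_csv(p)

    def test_hydraulics_reader_bounds_slope(self, tmp_path):
        p = tmp_path / "hyd.csv"
        p.write_text(
            "site_id,velocity_m_s,slope\na,0.5,0.01\nb,0.5,1.5\nc,-1,0.01\n"
        )
        df = read_hydraulics_csv(p)
        assert df["site_id"].tolist() == ["a"]

    def test_bundle_round_trips_through_csv(self, tmp_path, bundle_1980s):
        d = tmp_path / "bundle"
        bundle_1980s.write_csv(d)
        inv = read_inventory_csv(d / "stream_inventory.csv", water_type="stream")
        assert inv.total_m2() == pytest.approx(bundle_1980s.stream_inventory.total_m2())
        ice = read_ice_free_csv(d / "ice_free_days.csv")
        assert ice == {
            r: {s: float(v) for s, v in d2.items()}
            for r, d2 in bundle_1980s.ice_free_days.items()
        }

    def test_network_reader_marks_outlets(self, tmp_path):
        p = tmp_path / "net.csv"
        p.write_text(
            "segment_id,downstream_id,length_km,region\ns1,s3,1.0,Yangtze\n"
            "s2,s3,1.0,Yangtze\ns3,,2.0,Yangtze\n"
        )
        edges = read_network_csv(p)
        assert edges["s3"] is None and edges["s1"] == "s3"
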