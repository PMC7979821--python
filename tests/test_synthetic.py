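import numpy as np
import pandas as pd
import pytest

from aquaflux.hydrography import strahler_order
from aquaflux.scenarios import (
    HEADWATER_EFFLUX_SHARE,
    NATIONAL_AREAS_KM2,
    SUBTOTAL_EFFLUX,
    gen_scenario,
)
from aquaflux.synthetic import gen_gauges, gen_lentic, gen_network, gen_winds, mean_lentic_k600
from aquaflux.upscale import efflux_lentic, efflux_streams, order_group_shares, per_order_efflux


class TestGaugeGenerator:
    def test_deterministic_under_fixed_seed(self):
        c1, h1 = gen_gauges(seed=11, n_sites_per_order=(2, 2, 1, 1, 1, 1, 1, 1), n_obs_per_site=5)
        c2, h2 = gen_gauges(seed=11, n_sites_per_order=(2, 2, 1, 1, 1, 1, 1, 1), n_obs_per_site=5)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(h1, h2)

    def test_observation_count_exceeds_screening_threshold(self, gauge_tables):
        chem, _ = gauge_tables
        assert (chem.groupby("site_id").size() >= 25).all()

    def test_induced_pco2_population_envelope(self, gauge_site_fluxes):
        mean = gauge_site_fluxes["pco2_uatm"].mean()
        assert 2798 - 600 <= mean <= 2798 + 600
        assert gauge_site_fluxes["pco2_uatm"].min() >= 112
        assert gauge_site_fluxes["pco2_uatm"].max() <= 29_096

    def test_flux_declines_downstream_with_expected_step(self, gauge_site_fluxes):
        by_order = gauge_site_fluxes.groupby("stratum")["F_mmol_m2_d"].mean()
        assert (by_order.diff().dropna() < 0).all()
        step = (by_order.iloc[0] - by_order.iloc[-1]) / (len(by_order) - 1)
        assert 75 <= step <= 123

    def test_headwater_k600_population(self, gauge_site_fluxes):
        head = gauge_site_fluxes[gauge_site_fluxes["stratum"] <= 2]
        assert head["k600_cm_h"].mean() == pytest.approx(43.0, rel=0.2)
        assert gauge_site_fluxes["k600_cm_h"].min() >= 8.3
        assert gauge_site_fluxes["k600_cm_h"].max() <= 432.0

    def test_wet_season_flux_excess_in_band(self, gauge_site_fluxes):
        seasonal = gauge_site_fluxes.groupby("season")["F_mmol_m2_d"].mean()
        ratio = seasonal["wet"] / seasonal["dry"]
        assert 1.22 <= ratio <= 1.48

    def test_stream_k600_far_exceeds_lentic(self, gauge_site_fluxes):
        stream_median = gauge_site_fluxes["k600_cm_h"].median()
        winds = gen_winds(seed=2)
        lentic_median = np.median([mean_lentic_k600(np.array([u])) for u in winds[:200]])
        assert stream_median / lentic_median > 5.0


class TestNetworkGenerator:
    def test_geometric_counts(self):
        edges, _ = gen_network(horton_ratio=4, max_order=3)
        counts = edges.groupby("order").size()
        assert counts.tolist() == [16, 4, 1]

    def test_headwater_area_share_in_printed_band(self):
        _, strata = gen_network(seed=0)
        area = strata["total_length_km"] * 1000 * strata["width_dry_m"]
        share = area[strata["order"] <= 2].sum() / area.sum()
        assert 0.34 <= share <= 0.38

    def test_strahler_ordering_self_consistent(self):
        edges, _ = gen_network(horton_ratio=3, max_order=5, seed=1)
        mapping = {
            r.segment_id: (r.downstream_id or None) for r in edges.itertuples()
        }
        computed = strahler_order(mapping)
        declared = dict(zip(edges["segment_id"], edges["order"]))
        assert computed == declared

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            gen_network(horton_ratio=1)


class TestLenticGenerator:
    def test_undersaturated_share(self):
        _, sites = gen_lentic(seed=5, n_pco2_sites=500)
        assert sites["undersaturated"].mean() == pytest.approx(0.21, abs=0.03)

    def test_reservoir_expansion_between_periods(self):
        b80, _ = gen_lentic("1980s", seed=3)
        b10, _ = gen_lentic("2010s", seed=3)
        r80 = b80.loc[b80["kind"] == "reservoir", "area_km2"].sum()
        r10 = b10.loc[b10["kind"] == "reservoir", "area_km2"].sum()
        assert 100 * (r10 - r80) / r80 == pytest.approx(73.0, abs=1.0)

    def test_deterministic_under_fixed_seed(self):
        a = gen_lentic(seed=9)
        b = gen_lentic(seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_bodies_span_all_size_classes(self):
        bodies, _ = gen_lentic(seed=1)
        from aquaflux.hydrography import classify_lentic

        classes = bodies["area_km2"].map(classify_lentic).unique()
        assert set(classes) == {"small", "medium", "large"}


class TestScenarioRecovery:
    @pytest.mark.parametrize("period", ["1980s", "2010s"])
    def test_pipeline_recovers_generator_targets(self, period):
        b = gen_scenario(period)
        riv, _, cells = efflux_streams(b.stream_fluxes, b.stream_inventory, b.ice_free_days)
        lak, _, _ = efflux_lentic(b.lake_fluxes, b.lake_inventory, b.ice_free_days)
        res, _, _ = efflux_lentic(b.reservoir_fluxes, b.reservoir_inventory, b.ice_free_days)
        assert riv.value == pytest.approx(SUBTOTAL_EFFLUX[period]["rivers"][0], rel=0.02)
        assert lak.value == pytest.approx(SUBTOTAL_EFFLUX[period]["lakes"][0], rel=0.02)
        assert res.value == pytest.approx(SUBTOTAL_EFFLUX[period]["reservoirs"][0], rel=0.02)
        share = order_group_shares(per_order_efflux(cells))["headwater"]
        assert share == pytest.approx(HEADWATER_EFFLUX_SHARE[period], abs=0.05)

    def test_inventories_match_published_areas(self):
        for period in ("1980s", "2010s"):
            b = gen_scenario(period)
            for season, key in (("dry", "stream_dry"), ("wet", "stream_wet")):
                assert b.stream_inventory.total_km2(season) == pytest.approx(
                    NATIONAL_AREAS_KM2[period][key][0], rel=1e-9
                )
            assert b.lake_inventory.total_km2() == pytest.approx(
                NATIONAL_AREAS_KM2[period]["lakes"][0], rel=1e-9
            )

    def test_unknown_period_rejected(self):
        with pytest.raises(ValueError, match="period"):
            gen_scenario("1990s")

    def test_gauge_pipeline_recovers_order_targets(self, gauge_site_fluxes):
        """Stochastic parameter recovery: per-order mean fluxes track the
        generator's declining target profile once the seasonal mix is
        accounted for."""
        from aquaflux.synthetic import GaugeProfile

        p = GaugeProfile()
        step = (p.F_head - p.F_tail) / 7
        for order, grp in gauge_site_fluxes.groupby("stratum"):
            target = p.F_head - step * (order - 1)
            wet_frac = (grp["season"] == "wet").mean()
            expected = target * (1 + (p.wet_dry_ratio - 1) * wet_frac)
            n_sites = grp["site_id"].nunique()
            # three standard errors at the generator's site-level CV (~0.35
            # from the combined site, observation and hydraulics noise)
            bound = 3 * 0.35 / np.sqrt(n_sites)
            assert abs(grp["F_mmol_m2_d"].mean() / expected - 1) < bound
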