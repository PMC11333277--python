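import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pph_cea import costs as costs_mod
from pph_cea import daly as daly_mod
from pph_cea.cea import (
    budget_impact,
    ceac,
    cluster_bootstrap,
    default_thresholds,
    dsa_drape_price,
    icer,
    nmb,
    pooled_one_country_cua,
    wtp_thresholds,
)
from pph_cea.design import build_design, fit_design
from pph_cea.inference import adjusted_mean_difference
from pph_cea.records import AdjustedEstimate


class TestIcer:
    def test_ratio_of_published_rounded_differences(self):
        res = icer(0.30, 0.00266)
        assert res.status == "icer"
        assert res.icer == pytest.approx(112.78, abs=0.01)
        res2 = icer(0.30, 0.026)
        assert res2.icer == pytest.approx(11.54, abs=0.01)

    def test_dominance_statuses(self):
        assert icer(-0.01, 0.00266).status == "dominant"
        assert icer(5.0, -0.001).status == "dominated"
        assert icer(5.0, 0.0).status == "undefined"
        assert icer(-2.0, -0.001).status == "icer"  # cheaper and worse: a real trade-off

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            icer(np.nan, 1.0)

    @given(st.floats(min_value=1e-6, max_value=1e3), st.floats(min_value=1e-6, max_value=1e3))
    @settings(derandomize=True, max_examples=40)
    def test_dominance_invariant_to_positive_rescaling(self, a, b):
        for dc, de in [(-1.0, 0.5), (2.0, -0.3), (3.0, 0.7)]:
            assert icer(a * dc, b * de).status == icer(dc, de).status


class TestNmb:
    def test_arithmetic_at_opportunity_cost_threshold(self):
        assert nmb(0.30, 0.00266, 1690.0) == pytest.approx(1690 * 0.00266 - 0.30)
        assert nmb(0.30, 0.00266, 1690.0) == pytest.approx(4.195, abs=0.01)

    def test_lambda_zero_is_negative_cost(self):
        assert nmb(0.30, 0.5, 0.0) == -0.30

    @given(
        st.floats(min_value=-10, max_value=10),
        st.floats(min_value=1e-4, max_value=1.0),
        st.floats(min_value=0, max_value=5000),
    )
    @settings(derandomize=True, max_examples=40)
    def test_positive_nmb_iff_icer_below_lambda(self, dc, de, lam):
        res = icer(dc, de)
        if res.status == "icer" and de > 0:
            assert (nmb(dc, de, lam) > 0) == (res.icer < lam)


class TestThresholds:
    def test_country_shares(self):
        thr = wtp_thresholds({"kenya": 2000.0, "south_africa": 2000.0}, {"kenya": 0.51, "south_africa": 0.71}, {"kenya": 1.0, "south_africa": 1.0})
        assert thr.opportunity_cost_based["kenya"] == pytest.approx(1020.0)
        assert thr.opportunity_cost_based["south_africa"] == pytest.approx(1420.0)
        assert all(
            thr.opportunity_cost_based[c] < thr.gdp_based[c] for c in thr.gdp_based
        )

    def test_single_country_weight_collapses(self):
        thr = wtp_thresholds({"kenya": 1500.0}, {"kenya": 0.51}, {"kenya": 1.0})
        assert thr.weighted_gdp == 1500.0
        assert thr.weighted_opportunity_cost == pytest.approx(765.0)

    def test_default_config_reproduces_published_weighted_thresholds(self):
        thr = default_thresholds()
        assert thr.weighted_gdp == pytest.approx(2816.0, rel=0.01)
        assert thr.weighted_opportunity_cost == pytest.approx(1690.0, rel=0.01)

    def test_missing_share_raises(self):
        from pph_cea.costs import ConfigError

        with pytest.raises(ConfigError):
            wtp_thresholds({"kenya": 2000.0}, {}, {"kenya": 1.0})


class TestCeac:
    def _pairs(self):
        return pd.DataFrame(
            {
                "delta_cost": [1.0, -0.5, 2.0, -1.0],
                "delta_daly": [-0.02, -0.01, -0.005, 0.001],
            }
        )

    def test_hand_enumerated_probability_at_lambda_100(self):
        pairs = self._pairs()
        curve = ceac(pairs, np.array([0.0, 100.0]))
        # NMB at 100: 100*0.02-1=1>0; 100*0.01+0.5>0; 100*0.005-2<0; -0.1+1=0.9>0
        assert curve.at(100.0) == pytest.approx(3 / 4)

    def test_probability_at_zero_is_fraction_of_negative_cost(self):
        pairs = self._pairs()
        curve = ceac(pairs, np.array([0.0, 50.0]))
        assert curve.probability[0] == pytest.approx((pairs["delta_cost"] < 0).mean())

    def test_monotone_when_all_effects_positive(self):
        rng = np.random.default_rng(0)
        pairs = pd.DataFrame(
            {"delta_cost": rng.normal(0.3, 1.0, 200), "delta_daly": -np.abs(rng.normal(0.003, 0.002, 200))}
        )
        curve = ceac(pairs)
        assert (np.diff(curve.probability) >= -1e-12).all()

    def test_all_dominant_pairs_probability_one(self):
        pairs = pd.DataFrame({"delta_cost": [-1.0, -2.0], "delta_daly": [-0.01, -0.02]})
        curve = ceac(pairs, np.array([0.0, 1000.0, 5000.0]))
        assert all(p == 1.0 for p in curve.probability)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            ceac(pd.DataFrame({"delta_cost": [], "delta_daly": []}))


class TestBootstrap:
    def test_identity_bootstrap_reproduces_point_estimates(self, small_complete, unit_cost_table, life_tables, daly_params):
        clusters, cc = small_complete
        cost = costs_mod.patient_cost(cc, unit_cost_table)
        dal = daly_mod.attach_dalys(cc, daly_params, life_tables)
        pairs = cluster_bootstrap(cc, clusters, cost, dal, B=1, seed=0, identity=True)
        d = build_design(cc, clusters, "total_cost", values=cost)
        expect_cost = fit_design(d).coef("treat")
        d2 = build_design(cc, clusters, "dalys", values=dal)
        expect_daly = fit_design(d2).coef("treat")
        assert pairs["delta_cost"].iloc[0] == pytest.approx(expect_cost, rel=1e-6, abs=1e-9)
        assert pairs["delta_daly"].iloc[0] == pytest.approx(expect_daly, rel=1e-6, abs=1e-9)

    def test_same_seed_identical_pairs(self, small_complete, unit_cost_table, life_tables, daly_params):
        clusters, cc = small_complete
        cost = costs_mod.patient_cost(cc, unit_cost_table)
        dal = daly_mod.attach_dalys(cc, daly_params, life_tables)
        p1 = cluster_bootstrap(cc, clusters, cost, dal, B=10, seed=7)
        p2 = cluster_bootstrap(cc, clusters, cost, dal, B=10, seed=7)
        pd.testing.assert_frame_equal(p1, p2)

    def test_bootstrap_se_consistent_with_model_se(self, small_complete, unit_cost_table, life_tables, daly_params):
        """Bootstrap spread of the cost difference agrees with the Wald SE within 40%."""
        clusters, cc = small_complete
        cost = costs_mod.patient_cost(cc, unit_cost_table)
        dal = daly_mod.attach_dalys(cc, daly_params, life_tables)
        pairs = cluster_bootstrap(cc, clusters, cost, dal, B=150, seed=3)
        d = build_design(cc, clusters, "total_cost", values=cost)
        m = fit_design(d)
        ratio = pairs["delta_cost"].std() / m.se("treat")
        assert 0.6 < ratio < 1.6


class TestDsaAndCountry:
    def test_dsa_daly_row_constant_and_cost_decreasing(self, small_complete):
        clusters, cc = small_complete
        daly_est = AdjustedEstimate(point=-0.003, ci_low=-0.008, ci_high=0.002)
        table = dsa_drape_price(cc, clusters, daly_est, prices=(1.00, 0.75, 0.50), n_perm=50, seed=0)
        assert table["delta_daly"].nunique() == 1
        assert (np.diff(table["delta_cost"]) < 0).all()  # lower price, lower incremental cost

    def test_dsa_base_price_row_matches_base_analysis(self, small_complete, unit_cost_table):
        clusters, cc = small_complete
        daly_est = AdjustedEstimate(point=-0.003, ci_low=-0.008, ci_high=0.002)
        table = dsa_drape_price(cc, clusters, daly_est, prices=(), base_price=1.25, n_perm=50, seed=0)
        cost = costs_mod.patient_cost(cc, unit_cost_table)
        d = build_design(cc, clusters, "total_cost", values=cost)
        assert table["delta_cost"].iloc[0] == pytest.approx(fit_design(d).coef("treat"), rel=1e-6)

    def test_one_country_costing_with_pooled_tables_is_consistent(
        self, small_complete, unit_cost_table, life_tables, daly_params
    ):
        clusters, cc = small_complete
        thr = default_thresholds()
        res = pooled_one_country_cua(
            cc, clusters, "kenya", unit_cost_table, life_tables, daly_params, thr, n_perm=50, seed=0
        )
        assert res["country"] == "kenya"
        assert res["gdp_threshold"] == thr.gdp_based["kenya"]
        assert res["icer"]["status"] in {"icer", "dominant", "dominated", "undefined"}

    def test_doubling_unit_costs_doubles_cost_difference(
        self, small_complete, unit_cost_table, life_tables, daly_params
    ):
        from pph_cea.costs import UnitCostTable, single_country_table

        clusters, cc = small_complete
        one = single_country_table(unit_cost_table, "kenya")
        doubled = UnitCostTable(table=one.table * 2.0, provenance=one.provenance)
        c1 = costs_mod.patient_cost(cc, one)
        c2 = costs_mod.patient_cost(cc, doubled)
        d1 = build_design(cc, clusters, "total_cost", values=c1)
        d2 = build_design(cc, clusters, "total_cost", values=c2)
        # equality up to optimizer tolerance in the REML variance components
        assert fit_design(d2).coef("treat") == pytest.approx(2.0 * fit_design(d1).coef("treat"), rel=1e-4)

    def test_lower_life_expectancy_shrinks_daly_magnitude(self, small_complete, daly_params):
        from pph_cea.daly import LifeTable, attach_dalys

        clusters, cc = small_complete
        hi = LifeTable(country="x", ages=(15.0, 49.0), remaining_le=(55.0, 25.0))
        lo = LifeTable(country="x", ages=(15.0, 49.0), remaining_le=(30.0, 12.0))
        d_hi = attach_dalys(cc, daly_params, {c: hi for c in set(cc["country"])})
        d_lo = attach_dalys(cc, daly_params, {c: lo for c in set(cc["country"])})
        assert d_lo.sum() <= d_hi.sum()


class TestBudgetImpact:
    def test_arithmetic(self):
        out = budget_impact(0.30, {"kenya": 10_000})
        assert out["per_country"]["kenya"] == pytest.approx(3000.0)
        assert out["total"] == pytest.approx(3000.0)

    def test_zero_and_negative_sign_convention(self):
        assert budget_impact(0.0, {"a": 5000})["total"] == 0.0
        assert budget_impact(-0.5, {"a": 1000, "b": 1000})["total"] == pytest.approx(-1000.0)
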