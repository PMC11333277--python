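import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from pph_cea.design import DesignError, build_design, fit_design, standardize_cluster_covariates
from pph_cea.synth import TrialScenario, generate_trial


def _gaussian_trial_with_known_effects(seed=2, effect=1.5, sc_sd=0.8, sp_sd=0.4, resid=1.2):
    scenario = TrialScenario(
        clusters_per_country_per_arm={"kenya": 4, "nigeria": 4, "south_africa": 4, "tanzania": 4},
        patients_per_cluster_per_phase=60,
        seed=5,
    )
    clusters, records = generate_trial(scenario)
    cc = records[records["blood_loss_ml"].notna()].copy()
    rng = np.random.default_rng(seed)
    ids = sorted(clusters["cluster_id"])
    u = dict(zip(ids, rng.normal(0, sc_sd, len(ids))))
    v = {(c, p): rng.normal(0, sp_sd) for c in ids for p in ("baseline", "implementation")}
    treat = ((cc["arm"] == "intervention") & (cc["phase"] == "implementation")).astype(float)
    cc["y"] = (
        effect * treat
        + cc["cluster_id"].map(u).to_numpy()
        + np.array([v[(c, p)] for c, p in zip(cc["cluster_id"], cc["phase"])])
        + rng.normal(0, resid, len(cc))
    )
    return clusters, cc


class TestGaussian:
    def test_matches_statsmodels_mixedlm(self):
        """Cell-statistic REML must agree with a full MixedLM fit on raw records."""
        clusters, cc = _gaussian_trial_with_known_effects()
        d = build_design(cc, clusters, "total_cost", values=cc["y"])
        mine = fit_design(d)

        df = cc.copy()
        df["treat"] = ((df["arm"] == "intervention") & (df["phase"] == "implementation")).astype(float)
        df["cp"] = df["cluster_id"] + ":" + df["phase"]
        cs = standardize_cluster_covariates(clusters).set_index("cluster_id")
        for z in ("z_annual_vaginal_births", "z_baseline_event_proportion", "z_oxytocin_quality"):
            df[z] = df["cluster_id"].map(cs[z])
        ref = smf.mixedlm(
            "y ~ treat + C(phase) + C(country) + z_annual_vaginal_births"
            " + z_baseline_event_proportion + z_oxytocin_quality",
            df,
            groups=df["cluster_id"],
            re_formula="1",
            vc_formula={"cp": "0 + C(cp)"},
        ).fit(reml=True)

        assert mine.coef("treat") == pytest.approx(ref.fe_params["treat"], abs=1e-3)
        assert mine.sigma_cluster == pytest.approx(np.sqrt(float(ref.cov_re.iloc[0, 0])), rel=0.02)
        assert mine.sigma_cluster_period == pytest.approx(np.sqrt(float(ref.vcomp[0])), rel=0.02)
        assert mine.sigma_resid == pytest.approx(np.sqrt(ref.scale), rel=0.01)
        assert mine.se("treat", robust=False) == pytest.approx(ref.bse["treat"], rel=0.05)

    def test_zero_components_reduce_to_ols(self):
        clusters, cc = _gaussian_trial_with_known_effects(sc_sd=0.0, sp_sd=0.0)
        d = build_design(cc, clusters, "total_cost", values=cc["y"])
        mine = fit_design(d, fix_theta=(0.0, 0.0))
        # GLS at theta=0 equals WLS of cell means weighted by cell size
        ols = sm.WLS(d.cells["y_mean"], d.X, weights=d.cells["n"]).fit()
        np.testing.assert_allclose(mine.beta, ols.params, rtol=1e-6, atol=1e-7)

    def test_variance_component_boundary_is_flagged(self):
        clusters, cc = _gaussian_trial_with_known_effects(sc_sd=0.0, sp_sd=0.0)
        m = fit_design(build_design(cc, clusters, "total_cost", values=cc["y"]))
        assert m.boundary["sigma_cluster"] or m.sigma_cluster < 0.05

    def test_outcome_rescaling_equivariance(self):
        clusters, cc = _gaussian_trial_with_known_effects()
        d1 = build_design(cc, clusters, "total_cost", values=cc["y"])
        d2 = build_design(cc, clusters, "total_cost", values=1000.0 * cc["y"])
        m1, m2 = fit_design(d1), fit_design(d2)
        assert m2.coef("treat") == pytest.approx(1000.0 * m1.coef("treat"), rel=1e-4)
        assert m2.se("treat") == pytest.approx(1000.0 * m1.se("treat"), rel=1e-3)

    def test_robust_and_model_se_close_under_correct_model(self):
        """Balanced Gaussian clusters: sandwich and model SEs agree within ~35%."""
        rels = []
        for seed in (3, 4, 5):
            clusters, cc = _gaussian_trial_with_known_effects(seed=seed)
            m = fit_design(build_design(cc, clusters, "total_cost", values=cc["y"]))
            rels.append(m.se("treat") / m.se("treat", robust=False))
        assert 0.6 < np.mean(rels) < 1.4


class TestBinomial:
    def test_zero_variance_limit_matches_glm(self):
        scenario = TrialScenario(
            clusters_per_country_per_arm={"kenya": 4, "nigeria": 4, "south_africa": 4, "tanzania": 4},
            patients_per_cluster_per_phase=400,
            cluster_sd=0.0,
            cluster_period_sd=0.0,
            seed=9,
        )
        clusters, records = generate_trial(scenario)
        cc = records[records["blood_loss_ml"].notna()]
        d = build_design(cc, clusters, "severe_pph")
        mine = fit_design(d, fix_theta=(1e-4, 1e-4))
        glm = sm.GLM(
            np.column_stack([d.cells["events"], d.cells["n"] - d.cells["events"]]),
            d.X,
            family=sm.families.Binomial(),
        ).fit()
        np.testing.assert_allclose(mine.beta, glm.params, atol=1e-5)

    def test_recovers_treatment_log_odds_with_random_effects(self):
        """Across replicates the treatment estimate is within 3 MC s.e. of truth."""
        from pph_cea.synth import solve_logit_intercept

        scenario = TrialScenario(
            clusters_per_country_per_arm={"kenya": 5, "nigeria": 5, "south_africa": 5, "tanzania": 5},
            patients_per_cluster_per_phase=400,
            cluster_sd=0.3,
            seed=0,
        )
        sigma = np.hypot(scenario.cluster_sd, scenario.cluster_period_sd)
        truth = solve_logit_intercept(0.043 - 0.026, sigma) - solve_logit_intercept(0.043, sigma)
        ests = []
        for s in range(12):
            clusters, records = generate_trial(scenario, seed=400 + s)
            cc = records[records["blood_loss_ml"].notna()]
            m = fit_design(build_design(cc, clusters, "severe_pph"))
            ests.append(m.coef("treat"))
        err = np.mean(ests) - truth
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(err) < 3 * mc_se + 0.02

    def test_boundary_pinned_and_flagged_when_truth_is_zero(self):
        scenario = TrialScenario(
            clusters_per_country_per_arm={"kenya": 4, "nigeria": 4, "south_africa": 4, "tanzania": 4},
            patients_per_cluster_per_phase=500,
            cluster_sd=0.0,
            cluster_period_sd=0.0,
            seed=13,
        )
        clusters, records = generate_trial(scenario)
        cc = records[records["blood_loss_ml"].notna()]
        m = fit_design(build_design(cc, clusters, "severe_pph"))
        assert m.sigma_cluster < 0.08
        assert m.converged


class TestDesign:
    def test_constrained_baseline_indicator(self, small_complete):
        clusters, cc = small_complete
        d = build_design(cc, clusters, "severe_pph")
        treat = d.X[:, d.columns.index("treat")]
        base = (d.cells["phase"] == "baseline").to_numpy()
        uc = (d.cells["arm"] == "usual_care").to_numpy()
        assert (treat[base] == 0).all()
        assert (treat[uc] == 0).all()
        impl_int = (~base) & (d.cells["arm"] == "intervention").to_numpy()
        assert (treat[impl_int] == 1).all()

    def test_cluster_covariates_standardized(self, small_complete):
        clusters, cc = small_complete
        cs = standardize_cluster_covariates(clusters)
        for z in ("z_annual_vaginal_births", "z_baseline_event_proportion", "z_oxytocin_quality"):
            assert cs[z].mean() == pytest.approx(0.0, abs=1e-12)
            assert cs[z].std(ddof=0) == pytest.approx(1.0, rel=1e-9)

    def test_missing_phase_cluster_is_a_design_error(self, small_complete):
        clusters, cc = small_complete
        drop_one = cc[
            ~((cc["cluster_id"] == clusters["cluster_id"].iloc[0]) & (cc["phase"] == "baseline"))
        ]
        with pytest.raises(DesignError, match="phase"):
            build_design(drop_one, clusters, "severe_pph")

    def test_nan_outcome_refused(self, small_trial):
        _, clusters, records = small_trial
        with pytest.raises(DesignError):
            build_design(records, clusters, "severe_pph")
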