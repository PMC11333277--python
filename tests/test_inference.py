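import itertools

import numpy as np
import pandas as pd
import pytest

from pph_cea import costs as costs_mod
from pph_cea.design import build_design, fit_design
from pph_cea.inference import (
    impute_and_pool,
    marginal_risk_difference,
    adjusted_mean_difference,
    permutation_ci,
    permutation_pvalue,
    rubin_pool,
)
from pph_cea.synth import TrialScenario, generate_trial


class TestMarginalStandardization:
    def test_collapsibility_with_treatment_only_model(self):
        """Intercept+treatment logistic model: marginal RD equals raw risk difference."""
        rng = np.random.default_rng(4)
        n = np.array([500.0, 500.0, 480.0, 520.0])
        treat = np.array([0.0, 0.0, 1.0, 1.0])
        events = np.array([rng.binomial(int(m), 0.04 if t == 0 else 0.018) for m, t in zip(n, treat)], float)
        from pph_cea.glmm import fit_binomial
        from pph_cea.design import Design

        X = np.column_stack([np.ones(4), treat])
        model = fit_binomial(X, ["intercept", "treat"], events, n, np.array([0, 1, 2, 3]), fix_theta=(0.0, 0.0))
        cells = pd.DataFrame({"n": n, "phase": "implementation"})
        design = Design(
            family="binomial_logit", outcome="severe_pph", cells=cells, X=X,
            columns=["intercept", "treat"], cluster_code=np.array([0, 1, 2, 3]),
            cluster_ids=["a", "b", "c", "d"], n_records=int(n.sum()),
        )
        rd = marginal_risk_difference(model, design)
        raw = events[treat == 1].sum() / n[treat == 1].sum() - events[treat == 0].sum() / n[treat == 0].sum()
        assert rd.point == pytest.approx(100 * raw, abs=1e-6)

    def test_zero_treatment_coefficient_gives_zero_rd(self, small_complete):
        clusters, cc = small_complete
        d = build_design(cc, clusters, "severe_pph")
        m = fit_design(d)
        m.beta[m.columns.index("treat")] = 0.0
        rd = marginal_risk_difference(m, d)
        assert rd.point == pytest.approx(0.0, abs=1e-12)

    def test_published_implementation_counts_give_unadjusted_difference(self):
        """Raw arithmetic on the published event counts lands near the adjusted value."""
        from pph_cea import trial_summary as ts

        raw = (
            ts.SEVERE_PPH_EVENTS["intervention"] / ts.SEVERE_PPH_DENOMINATOR["intervention"]
            - ts.SEVERE_PPH_EVENTS["usual_care"] / ts.SEVERE_PPH_DENOMINATOR["usual_care"]
        )
        assert 100 * raw == pytest.approx(-2.64, abs=0.005)
        assert 100 * raw == pytest.approx(ts.ADJUSTED_RISK_DIFFERENCE_PP[0], abs=0.1)


class TestPermutation:
    def _cost_design(self, clusters, records):
        cc = records[records["blood_loss_ml"].notna()]
        cost = costs_mod.patient_cost(cc, costs_mod.default_unit_cost_table())
        d = build_design(cc, clusters, "total_cost", values=cost)
        return d, fit_design(d)

    def test_point_estimate_inside_its_own_ci(self, small_trial):
        _, clusters, records = small_trial
        d, m = self._cost_design(clusters, records)
        est = permutation_ci(d, clusters, model=m, n_perm=200, seed=4)
        assert est.ci_low <= est.point <= est.ci_high
        assert est.method == "permutation"

    def test_exhaustive_pvalue_matches_brute_force(self, eight_cluster_trial):
        """On an 8-cluster fixture the permutation p-value equals full enumeration."""
        clusters, records = eight_cluster_trial
        d, m = self._cost_design(clusters, records)
        p_mine = permutation_pvalue(d, clusters, model=m, delta=0.0, n_perm=200, seed=0)

        # independent brute force: dense-matrix GLS per assignment
        sc, sp, se2 = m.sigma_cluster, m.sigma_cluster_period, m.sigma_resid**2
        cells = d.cells
        n = cells["n"].to_numpy(float)
        code = d.cluster_code
        V = np.diag(sp**2 + se2 / n) + (sc**2) * (code[:, None] == code[None, :])
        Vinv = np.linalg.inv(V)
        y = cells["y_mean"].to_numpy(float)
        j = d.columns.index("treat")
        impl = (cells["phase"] == "implementation").to_numpy()

        meta = clusters.set_index("cluster_id")
        ids = np.array(d.cluster_ids)
        stats = []
        strata = {}
        for i, cid in enumerate(ids):
            strata.setdefault(meta.loc[cid, "country"], []).append(i)
        combos = []
        for country, idx in sorted(strata.items()):
            n_int = int((meta.loc[ids[idx], "arm"] == "intervention").sum())
            combos.append([set(c) for c in itertools.combinations(idx, n_int)])
        for combo in itertools.product(*combos):
            chosen = set().union(*combo)
            lab = np.isin(code, list(chosen))
            X = d.X.copy()
            X[:, j] = (lab & impl).astype(float)
            beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
            stats.append(beta[j])
        stats = np.abs(np.array(stats))
        t_obs = abs(m.coef("treat"))
        p_brute = float(np.mean(stats >= t_obs - 1e-12))
        assert p_mine == pytest.approx(p_brute, abs=1e-12)

    def test_sampled_pvalue_converges_to_exhaustive(self, eight_cluster_trial):
        """Force sampling on the small fixture; p-value approaches the exact one."""
        import pph_cea.inference as inf

        clusters, records = eight_cluster_trial
        d, m = self._cost_design(clusters, records)
        p_exact = permutation_pvalue(d, clusters, model=m, n_perm=200, seed=0)

        stat = inf._FastGaussianStat(d, m)
        strata = inf._strata(d, clusters)
        t_obs = abs(m.coef("treat"))
        errs = []
        for n_perm in (200, 1000, 5000):
            rng = np.random.default_rng(12)
            labels = inf._sample_assignments(strata, len(d.cluster_ids), n_perm, rng)
            t_perm = np.abs(np.array([stat.coefs(lab)[0] for lab in labels]))
            p = (np.sum(t_perm >= t_obs - 1e-12) + 1) / (n_perm + 1)
            errs.append(abs(p - p_exact))
        assert errs[2] < errs[0] + 0.02
        assert errs[2] < 0.03

    def test_baseline_only_data_is_invariant_to_arm_labels(self, small_trial):
        """Constrained baseline: treatment is not identified from baseline data alone."""
        _, clusters, records = small_trial
        base = records[(records["phase"] == "baseline") & records["blood_loss_ml"].notna()]
        cost = costs_mod.patient_cost(base, costs_mod.default_unit_cost_table())
        from pph_cea.design import DesignError

        with pytest.raises(DesignError):
            build_design(base, clusters, "total_cost", values=cost)


class TestRubin:
    def test_hand_worked_three_imputation_example(self):
        point, total_var, df = rubin_pool(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]))
        assert point == pytest.approx(2.0)
        assert total_var == pytest.approx(1.0 + (1 + 1 / 3) * 1.0)  # 2.3333
        assert np.isfinite(df)

    def test_identical_estimates_collapse_to_single_fit(self):
        point, total_var, df = rubin_pool(np.array([1.5, 1.5, 1.5]), np.array([0.04, 0.04, 0.04]))
        assert point == 1.5
        assert total_var == pytest.approx(0.04)
        assert df == np.inf

    def test_requires_at_least_two(self):
        with pytest.raises(ValueError):
            rubin_pool(np.array([1.0]), np.array([1.0]))


class TestImputeAndPool:
    def test_no_missingness_returns_complete_case_estimate(self, small_complete):
        clusters, cc = small_complete
        est = impute_and_pool(cc, clusters, "severe_pph", m=3, seed=0)
        d = build_design(cc, clusters, "severe_pph")
        direct = marginal_risk_difference(fit_design(d), d)
        assert est.method == "rubin_pooled"
        assert est.point == pytest.approx(direct.point, abs=1e-9)
        assert "notice" in est.extra

    def test_pooled_estimate_near_complete_case_with_light_missingness(self, small_trial):
        _, clusters, records = small_trial
        est = impute_and_pool(records, clusters, "severe_pph", m=3, seed=1)
        cc = records[records["blood_loss_ml"].notna()]
        d = build_design(cc, clusters, "severe_pph")
        direct = marginal_risk_difference(fit_design(d), d)
        # ~2% missingness: pooled point within one SE of the complete-case point
        assert abs(est.point - direct.point) < direct.se
        assert est.n_reps == 3
        assert est.se >= 0.9 * direct.se  # imputation cannot shrink uncertainty much

    def test_m_below_two_rejected(self, small_trial):
        _, clusters, records = small_trial
        with pytest.raises(ValueError):
            impute_and_pool(records, clusters, "severe_pph", m=1, seed=0)
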