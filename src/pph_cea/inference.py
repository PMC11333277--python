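"""Adjusted between-arm differences and their uncertainty.

Three inferential routes, matching how skewed per-patient costs/DALYs and a
binary severe-PPH outcome are handled in cluster trials:

* binomial outcome: Laplace GLMM fit -> marginal standardization to a risk
  difference (predicted risks averaged over the analysed sample with the
  exposure set to 1 vs 0 and random effects at their conditional mode of
  zero), delta-method CI on the cluster-robust covariance;
* Gaussian outcomes: treatment coefficient with a CI from inverting
  nonparametric permutation tests — cluster arm labels re-randomized within
  country strata, two-sided p-value, CI bounds where the p-value for
  H0: effect = delta crosses alpha (exhaustive enumeration when the number
  of distinct assignments is small);
* missing blood loss: predictive-mean-matching multiple imputation with
  cluster indicators among the predictors, estimates pooled by Rubin's rules
  with Barnard-Rubin degrees of freedom.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .design import Design, DesignError, build_design, fit_design
from .glmm import FittedModel
from .records import AdjustedEstimate, SEVERE_THRESHOLD_ML

EXHAUSTIVE_LIMIT = 20_000


# --------------------------------------------------------------------------
# marginal standardization / mean differences
# --------------------------------------------------------------------------


def _crit(model: FittedModel, alpha: float) -> float:
    """Critical value: t with clusters-minus-parameters df (normal fallback)."""
    df = model.n_clusters - len(model.columns)
    if df > 2:
        return float(stats.t.ppf(1 - alpha / 2, df))
    return float(stats.norm.ppf(1 - alpha / 2))


def marginal_risk_difference(model: FittedModel, design: Design, alpha: float = 0.05) -> AdjustedEstimate:
    """Adjusted risk difference in percentage points by marginal standardization."""
    if model.family != "binomial_logit":
        raise ValueError("marginal standardization requires the binomial model")
    X1 = design.X.copy()
    X0 = design.X.copy()
    j = design.columns.index("treat")
    X1[:, j] = 1.0
    X0[:, j] = 0.0
    w = design.cells["n"].to_numpy(float)
    w = w / w.sum()
    p1 = expit(X1 @ model.beta)
    p0 = expit(X0 @ model.beta)
    rd = float(w @ (p1 - p0))
    grad = (w * p1 * (1 - p1)) @ X1 - (w * p0 * (1 - p0)) @ X0
    se = float(np.sqrt(grad @ model.cov_robust @ grad))
    z = _crit(model, alpha)
    return AdjustedEstimate(
        point=100 * rd,
        ci_low=100 * (rd - z * se),
        ci_high=100 * (rd + z * se),
        alpha=alpha,
        method="model_wald",
        se=100 * se,
    )


def adjusted_mean_difference(model: FittedModel, alpha: float = 0.05, robust: bool = True) -> AdjustedEstimate:
    """Treatment coefficient of an identity-link model with a Wald CI."""
    if model.family != "gaussian_identity":
        raise ValueError("adjusted mean difference requires the Gaussian model")
    point = model.coef("treat")
    se = model.se("treat", robust=robust)
    z = _crit(model, alpha)
    return AdjustedEstimate(
        point=point, ci_low=point - z * se, ci_high=point + z * se, alpha=alpha,
        method="model_wald", se=se,
    )


# --------------------------------------------------------------------------
# permutation-test confidence intervals (Gaussian outcomes)
# --------------------------------------------------------------------------


def _strata(design: Design, clusters: pd.DataFrame) -> list[tuple[np.ndarray, int]]:
    """(cluster indices, number of intervention labels) per country stratum."""
    meta = clusters.set_index("cluster_id")
    out = []
    ids = np.array(design.cluster_ids)
    for country in sorted(meta.loc[ids, "country"].unique()):
        idx = np.flatnonzero(meta.loc[ids, "country"].to_numpy() == country)
        n_int = int((meta.loc[ids[idx], "arm"] == "intervention").sum())
        if n_int == 0 or n_int == len(idx):
            raise DesignError(f"degenerate stratum {country!r}: all clusters in one arm")
        out.append((idx, n_int))
    return out


def _n_assignments(strata) -> int:
    total = 1
    for idx, n_int in strata:
        total *= math.comb(len(idx), n_int)
        if total > 10 * EXHAUSTIVE_LIMIT:
            break
    return total


def _iter_assignments(strata, n_clusters):
    """Yield boolean intervention-label vectors for every within-stratum assignment."""
    per = [
        [set(c) for c in itertools.combinations(range(len(idx)), n_int)]
        for idx, n_int in strata
    ]
    for combo in itertools.product(*per):
        lab = np.zeros(n_clusters, dtype=bool)
        for (idx, _), chosen in zip(strata, combo):
            lab[idx[list(chosen)]] = True
        yield lab


def _sample_assignments(strata, n_clusters, n_perm, rng):
    out = np.zeros((n_perm, n_clusters), dtype=bool)
    for idx, n_int in strata:
        for b in range(n_perm):
            out[b, rng.choice(idx, size=n_int, replace=False)] = True
    return out


class _FastGaussianStat:
    """Per-assignment GLS treatment coefficient with frozen variance components.

    With the variance components held at their observed-data estimates, the
    statistic is an affine function of the null shift delta, so CI inversion
    by bisection costs nothing beyond the initial pass over assignments.
    """

    def __init__(self, design: Design, model: FittedModel):
        from .glmm import _gaussian_reml_parts

        self.design = design
        n = design.cells["n"].to_numpy(float)
        se2 = model.sigma_resid**2
        sc, sp = model.sigma_cluster, model.sigma_cluster_period
        d = sp * sp + se2 / n
        self.inv_d = 1.0 / d
        code = design.cluster_code
        C = int(code.max()) + 1
        s = np.bincount(code, weights=self.inv_d, minlength=C)
        self.w = (sc * sc) / (1.0 + sc * sc * s)
        self.code, self.C = code, C
        self.j = design.columns.index("treat")
        self.y = design.cells["y_mean"].to_numpy(float)
        self.t_obs = design.X[:, self.j].copy()

    def _gls_coef(self, X, vec):
        inv_d, w, code, C = self.inv_d, self.w, self.code, self.C
        Xw = X * inv_d[:, None]
        Tx = np.zeros((C, X.shape[1]))
        np.add.at(Tx, code, Xw)
        XtViX = X.T @ Xw - (Tx.T * w) @ Tx
        tv = np.bincount(code, weights=vec * inv_d, minlength=C)
        XtViv = Xw.T @ vec - Tx.T @ (w * tv)
        return float(np.linalg.solve(XtViX, XtViv)[self.j])

    def coefs(self, treat_labels: np.ndarray):
        """(a, c) such that the statistic under shift delta is a - delta * c."""
        X = self.design.X.copy()
        impl = (self.design.cells["phase"] == "implementation").to_numpy()
        X[:, self.j] = (treat_labels[self.code] & impl).astype(float)
        return self._gls_coef(X, self.y), self._gls_coef(X, self.t_obs)


def permutation_ci(
    design: Design,
    clusters: pd.DataFrame,
    model: FittedModel | None = None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    tol_factor: float = 1e-3,
) -> AdjustedEstimate:
    """Permutation-test CI for the treatment effect on a Gaussian outcome.

    Tests H0: effect = delta by subtracting delta from treated cells and
    re-estimating the treatment coefficient under re-randomized cluster arm
    labels within country strata; p-values use the (b+1)/(n+1) estimator for
    sampled permutations and the exact proportion under exhaustive
    enumeration.  CI bounds are found by bisection in delta.
    """
    if design.family != "gaussian_identity":
        raise ValueError("permutation CI implemented for Gaussian outcomes")
    if model is None:
        model = fit_design(design)
    stat = _FastGaussianStat(design, model)
    strata = _strata(design, clusters)
    n_clusters = len(design.cluster_ids)

    n_total = _n_assignments(strata)
    exhaustive = n_total <= min(EXHAUSTIVE_LIMIT, 20 * n_perm) or n_clusters < 6
    if exhaustive:
        labels = np.array(list(_iter_assignments(strata, n_clusters)))
    else:
        rng = np.random.default_rng(seed)
        labels = _sample_assignments(strata, n_clusters, n_perm, rng)

    ac = np.array([stat.coefs(lab) for lab in labels])  # B x 2
    a, c = ac[:, 0], ac[:, 1]
    point = model.coef("treat")

    def pvalue(delta: float) -> float:
        t_obs = abs(point - delta)
        t_perm = np.abs(a - delta * c)
        if exhaustive:
            return float(np.mean(t_perm >= t_obs - 1e-12))
        b = int(np.sum(t_perm >= t_obs - 1e-12))
        return (b + 1.0) / (len(t_perm) + 1.0)

    sd_y = float(np.std(design.cells["y_mean"])) or 1.0
    tol = tol_factor * sd_y
    span = max(10 * model.se("treat"), 10 * sd_y, 1e-6)

    def search(direction: int) -> float:
        lo, hi = point, point + direction * span
        # widen until rejection
        for _ in range(60):
            if pvalue(hi) < alpha:
                break
            hi += direction * span
        else:
            return hi  # no rejection found; report the scanned bound
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if pvalue(mid) >= alpha:
                lo = mid
            else:
                hi = mid
            if abs(hi - lo) < tol:
                break
        return 0.5 * (lo + hi)

    ci_low, ci_high = sorted((search(-1), search(+1)))
    return AdjustedEstimate(
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        alpha=alpha,
        method="permutation",
        n_reps=len(labels),
        seed=seed,
        se=model.se("treat"),
        extra={"exhaustive": exhaustive, "p_at_zero": pvalue(0.0)},
    )


def permutation_pvalue(design, clusters, model=None, delta: float = 0.0, n_perm: int = 1000, seed: int = 0):
    """Two-sided permutation p-value for H0: effect = delta."""
    if model is None:
        model = fit_design(design)
    stat = _FastGaussianStat(design, model)
    strata = _strata(design, clusters)
    n_clusters = len(design.cluster_ids)
    n_total = _n_assignments(strata)
    exhaustive = n_total <= min(EXHAUSTIVE_LIMIT, 20 * n_perm) or n_clusters < 6
    if exhaustive:
        labels = np.array(list(_iter_assignments(strata, n_clusters)))
    else:
        rng = np.random.default_rng(seed)
        labels = _sample_assignments(strata, n_clusters, n_perm, rng)
    ac = np.array([stat.coefs(lab) for lab in labels])
    t_perm = np.abs(ac[:, 0] - delta * ac[:, 1])
    t_obs = abs(model.coef("treat") - delta)
    if exhaustive:
        return float(np.mean(t_perm >= t_obs - 1e-12))
    return (int(np.sum(t_perm >= t_obs - 1e-12)) + 1.0) / (len(t_perm) + 1.0)


# --------------------------------------------------------------------------
# multiple imputation + Rubin's rules
# --------------------------------------------------------------------------


def rubin_pool(points: np.ndarray, variances: np.ndarray, alpha: float = 0.05, df_com: float | None = None):
    """Rubin's rules for m completed-data estimates.

    Returns (pooled point, total variance, degrees of freedom).  Total
    variance is W + (1 + 1/m) B; df by Barnard-Rubin when a complete-data df
    is supplied, otherwise the classic large-sample formula.
    """
    points = np.asarray(points, float)
    variances = np.asarray(variances, float)
    m = len(points)
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 estimates")
    qbar = float(points.mean())
    wbar = float(variances.mean())
    b = float(points.var(ddof=1))
    t = wbar + (1 + 1 / m) * b
    if b == 0.0:
        return qbar, t, np.inf
    r = (1 + 1 / m) * b / wbar if wbar > 0 else np.inf
    df_old = (m - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) else m - 1
    if df_com is None:
        return qbar, t, df_old
    lam = (1 + 1 / m) * b / t
    df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
    df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    return qbar, t, df


def _pmm_impute(records: pd.DataFrame, clusters: pd.DataFrame, rng: np.random.Generator, k_pmm: int = 5) -> pd.DataFrame:
    """One predictive-mean-matching imputation of missing blood loss.

    Proper imputation: the linear predictor is refitted on a bootstrap
    resample of complete cases; predictors are the treatment exposure, period
    and cluster indicators (the latter being the clustering allowance).
    """
    df = records.copy()
    miss = df["blood_loss_ml"].isna()
    if not miss.any():
        return df
    treat = ((df["arm"] == "intervention") & (df["phase"] == "implementation")).astype(float)
    period = (df["phase"] == "implementation").astype(float)
    Xfull = pd.get_dummies(df["cluster_id"], prefix="cl", dtype=float)
    Xfull.insert(0, "treat", treat)
    Xfull.insert(1, "period", period)
    X = Xfull.to_numpy()
    y = df["blood_loss_ml"].to_numpy()

    obs = np.flatnonzero(~miss)
    mis = np.flatnonzero(miss.to_numpy())
    boot = rng.choice(obs, size=len(obs), replace=True)
    beta, *_ = np.linalg.lstsq(X[boot], y[boot], rcond=None)
    pred = X @ beta
    donor_pred = pred[obs]
    order = np.argsort(donor_pred)
    sorted_pred = donor_pred[order]
    for i in mis:
        pos = np.searchsorted(sorted_pred, pred[i])
        lo = max(0, pos - k_pmm)
        hi = min(len(obs), pos + k_pmm)
        pool = order[lo:hi]
        donor = pool[rng.integers(len(pool))]
        df.iloc[i, df.columns.get_loc("blood_loss_ml")] = y[obs[donor]]
    return df


def impute_and_pool(
    records: pd.DataFrame,
    clusters: pd.DataFrame,
    outcome: str,
    value_fn=None,
    m: int = 7,
    seed: int = 0,
    alpha: float = 0.05,
) -> AdjustedEstimate:
    """Multiply impute missing blood loss and pool the adjusted difference.

    ``value_fn(records) -> Series`` supplies the per-record Gaussian outcome
    recomputed on each completed dataset (e.g. DALYs, which depend on blood
    loss); ``outcome='severe_pph'`` pools the marginally standardized risk
    difference.  Within-imputation inference is the robust Wald variance.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    miss = records["blood_loss_ml"].isna()

    def estimate(df) -> AdjustedEstimate:
        if outcome == "severe_pph":
            d = build_design(df, clusters, "severe_pph")
            return marginal_risk_difference(fit_design(d), d, alpha=alpha)
        vals = value_fn(df)
        d = build_design(df, clusters, outcome, values=vals)
        return adjusted_mean_difference(fit_design(d), alpha=alpha)

    if not miss.any():
        est = estimate(records)
        return AdjustedEstimate(
            point=est.point, ci_low=est.ci_low, ci_high=est.ci_high, alpha=alpha,
            method="rubin_pooled", n_reps=0, seed=seed, se=est.se,
            extra={"notice": "no missing blood loss; complete-case estimate returned"},
        )

    rng = np.random.default_rng(seed)
    points, variances = [], []
    for _ in range(m):
        completed = _pmm_impute(records, clusters, rng)
        est = estimate(completed)
        points.append(est.point)
        variances.append(est.se**2)

    df_com = max(len(clusters) - 8, 1)
    qbar, t, df = rubin_pool(np.array(points), np.array(variances), df_com=df_com)
    tcrit = stats.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(t)
    return AdjustedEstimate(
        point=qbar, ci_low=qbar - tcrit * se, ci_high=qbar + tcrit * se,
        alpha=alpha, method="rubin_pooled", n_reps=m, seed=seed, se=se,
        extra={"df": float(df), "between_var": float(np.var(points, ddof=1))},
    )
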