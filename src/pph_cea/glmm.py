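"""Mixed models for the constrained-baseline cluster-trial design.

Two estimators over cluster-period cell data (all fixed effects in this
design are constant within a cluster-period cell, so individual-level data
can be reduced without loss to per-cell sufficient statistics):

* ``fit_binomial`` — logistic GLMM with random cluster and cluster-by-period
  intercepts, fitted by Laplace-approximate maximum likelihood: for each
  variance-component pair the fixed effects and random-effect modes are found
  by a joint penalized Newton solve (random-effect blocks eliminated by Schur
  complements, so the per-iteration cost is one dense p x p solve), and the
  two standard deviations are profiled by quasi-Newton on the Laplace
  criterion.

* ``fit_gaussian`` — linear mixed model with the same random structure,
  fitted by REML on cell means: the residual variance comes in closed form
  from the pooled within-cell sum of squares, and the two variance components
  are profiled on the cell-mean marginal likelihood (cell means carry
  heteroscedastic residual variance sigma_e^2 / n_cell).

Both report a model-based covariance and a cluster-robust (CR1 sandwich)
covariance with hospitals as the independent units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

_SD_FLOOR = 1e-4  # variance-component boundary; estimates below 10x floor are flagged


class EstimationError(RuntimeError):
    pass


@dataclass
class FittedModel:
    family: str  # binomial_logit | gaussian_identity
    beta: np.ndarray
    columns: list[str]
    cov_model: np.ndarray
    cov_robust: np.ndarray
    sigma_cluster: float
    sigma_cluster_period: float
    sigma_resid: float | None
    loglik: float
    converged: bool
    boundary: dict = field(default_factory=dict)
    n_clusters: int = 0
    n_obs: int = 0
    diagnostics: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])

    def se(self, name: str, robust: bool = True) -> float:
        i = self.columns.index(name)
        cov = self.cov_robust if robust else self.cov_model
        return float(np.sqrt(cov[i, i]))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": dict(zip(self.columns, map(float, self.beta))),
            "sigma_cluster": self.sigma_cluster,
            "sigma_cluster_period": self.sigma_cluster_period,
            "sigma_resid": self.sigma_resid,
            "robust_se": {c: self.se(c) for c in self.columns},
            "loglik": self.loglik,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_clusters": self.n_clusters,
            "n_obs": self.n_obs,
        }


def _cluster_sums(code: np.ndarray, arr: np.ndarray, n_groups: int) -> np.ndarray:
    """Row-sum ``arr`` within groups: (M,...) -> (C,...)."""
    out = np.zeros((n_groups,) + arr.shape[1:])
    np.add.at(out, code, arr)
    return out


# --------------------------------------------------------------------------
# Gaussian REML on cell means
# --------------------------------------------------------------------------


def _gaussian_reml_parts(sc, sp, X, y, n, se2, code, C):
    """Accumulate GLS pieces for V = sc^2 J_cluster + diag(sp^2 + se2/n)."""
    d = sp * sp + se2 / n
    inv_d = 1.0 / d
    s = np.bincount(code, weights=inv_d, minlength=C)
    w = (sc * sc) / (1.0 + sc * sc * s)  # per-cluster Woodbury factor
    Xw = X * inv_d[:, None]
    Tx = _cluster_sums(code, Xw, C)  # C x p
    ty = np.bincount(code, weights=y * inv_d, minlength=C)
    XtViX = X.T @ Xw - (Tx.T * w) @ Tx
    XtViy = Xw.T @ y - Tx.T @ (w * ty)
    ytViy = float(np.sum(y * y * inv_d) - np.sum(w * ty * ty))
    logdet = float(np.sum(np.log(d)) + np.sum(np.log1p(sc * sc * s)))
    return XtViX, XtViy, ytViy, logdet, (inv_d, s, w)


def fit_gaussian(
    X: np.ndarray,
    columns: list[str],
    y_mean: np.ndarray,
    y_ssw: np.ndarray,
    n: np.ndarray,
    cluster_code: np.ndarray,
    fix_theta: tuple[float, float] | None = None,
) -> FittedModel:
    """REML fit of the Gaussian mixed model from cell sufficient statistics.

    Parameters are cell-level: mean outcome, within-cell sum of squares,
    cell size, and cluster membership.
    """
    X = np.asarray(X, float)
    y = np.asarray(y_mean, float)
    n = np.asarray(n, float)
    code = np.asarray(cluster_code)
    C = int(code.max()) + 1
    M, p = X.shape
    N = float(n.sum())

    se2 = float(np.sum(y_ssw) / (N - M)) if N > M else 0.0

    def crit(x):
        sc, sp = np.maximum(x, _SD_FLOOR)
        XtViX, XtViy, ytViy, logdet, _ = _gaussian_reml_parts(sc, sp, X, y, n, se2, code, C)
        try:
            beta = np.linalg.solve(XtViX, XtViy)
            sign, logdet_xvx = np.linalg.slogdet(XtViX)
        except np.linalg.LinAlgError:
            return 1e12
        if sign <= 0:
            return 1e12
        quad = ytViy - float(beta @ XtViy)
        return logdet + logdet_xvx + quad

    if fix_theta is not None:
        x_hat = np.maximum(np.asarray(fix_theta, float), _SD_FLOOR)
        ok = True
        nit = 0
    else:
        resid0 = y - y.mean()
        s0 = max(float(np.std(resid0)), 10 * _SD_FLOOR)
        res = minimize(
            crit,
            x0=np.array([0.5 * s0, 0.25 * s0]),
            method="L-BFGS-B",
            bounds=[(_SD_FLOOR, None)] * 2,
        )
        x_hat = np.maximum(res.x, _SD_FLOOR)
        ok = bool(res.success)
        nit = int(res.nit)

    sc, sp = float(x_hat[0]), float(x_hat[1])
    XtViX, XtViy, ytViy, logdet, (inv_d, s, w) = _gaussian_reml_parts(sc, sp, X, y, n, se2, code, C)
    beta = np.linalg.solve(XtViX, XtViy)
    cov_model = np.linalg.inv(XtViX)

    # CR1 cluster sandwich on the GLS estimating equations
    r = y - X @ beta
    Xw = X * inv_d[:, None]
    Tx = _cluster_sums(code, Xw, C)
    tr = np.bincount(code, weights=r * inv_d, minlength=C)
    G = _cluster_sums(code, Xw * r[:, None], C) - Tx * (w * tr)[:, None]  # C x p scores
    Gc = G - G.mean(axis=0)
    # small-sample factor G/(G-p): all fixed effects are cluster-level here
    B = Gc.T @ Gc * (C / max(C - p, 1))
    A_inv = cov_model
    cov_robust = A_inv @ B @ A_inv

    crit_val = crit(x_hat)
    return FittedModel(
        family="gaussian_identity",
        beta=beta,
        columns=list(columns),
        cov_model=cov_model,
        cov_robust=cov_robust,
        sigma_cluster=sc,
        sigma_cluster_period=sp,
        sigma_resid=float(np.sqrt(se2)),
        loglik=-0.5 * crit_val,
        converged=ok,
        boundary={
            "sigma_cluster": sc <= 10 * _SD_FLOOR,
            "sigma_cluster_period": sp <= 10 * _SD_FLOOR,
        },
        n_clusters=C,
        n_obs=int(N),
        diagnostics={"outer_iterations": nit, "reml_criterion": crit_val},
    )


# --------------------------------------------------------------------------
# Binomial Laplace
# --------------------------------------------------------------------------


def _binomial_inner(beta, u, v, X, yk, n, code, C, sc, sp, max_iter=50):
    """Joint penalized Newton over (beta, u, v); returns mode and pieces."""
    M, p = X.shape
    lam_u = 1.0 / (sc * sc)
    lam_v = 1.0 / (sp * sp)

    def pen_ll(beta, u, v):
        eta = np.clip(X @ beta + u[code] + v, -30, 30)
        ll = float(yk @ eta - n @ np.logaddexp(0.0, eta))
        return ll - 0.5 * lam_u * float(u @ u) - 0.5 * lam_v * float(v @ v)

    f = pen_ll(beta, u, v)
    for it in range(max_iter):
        eta = np.clip(X @ beta + u[code] + v, -30, 30)
        mu = n * expit(eta)
        W = n * expit(eta) * (1.0 - expit(eta))
        resid = yk - mu

        g_beta = X.T @ resid
        g_u = np.bincount(code, weights=resid, minlength=C) - lam_u * u
        g_v = resid - lam_v * v
        gnorm = max(np.abs(g_beta).max(), np.abs(g_u).max(), np.abs(g_v).max())
        if gnorm < 1e-8 * max(1.0, float(n.sum())):
            break

        Dv = W + lam_v
        a = W / Dv  # cell-level shrinkage of v
        Wt = W * (1.0 - a)  # W - W^2/Dv
        # Schur onto (beta, u) after eliminating v
        XW = X * Wt[:, None]
        S_bb = X.T @ XW
        S_bu = _cluster_sums(code, XW, C).T  # p x C
        S_uu = np.bincount(code, weights=Wt, minlength=C) + lam_u  # diagonal
        r_b = g_beta - X.T @ (a * g_v)
        r_u = g_u - np.bincount(code, weights=a * g_v, minlength=C)
        # eliminate u (diagonal)
        inv_Suu = 1.0 / S_uu
        A = S_bb - (S_bu * inv_Suu) @ S_bu.T
        rhs = r_b - S_bu @ (inv_Suu * r_u)
        try:
            db = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            raise EstimationError("singular system in penalized Newton step")
        du = inv_Suu * (r_u - S_bu.T @ db)
        dv = (g_v - W * (X @ db) - W * du[code]) / Dv

        step = 1.0
        for _ in range(30):
            f_new = pen_ll(beta + step * db, u + step * du, v + step * dv)
            if f_new >= f - 1e-10:
                break
            step *= 0.5
        beta = beta + step * db
        u = u + step * du
        v = v + step * dv
        f = f_new
    eta = np.clip(X @ beta + u[code] + v, -30, 30)
    W = n * expit(eta) * (1.0 - expit(eta))
    return beta, u, v, f, W, gnorm


def _laplace_logdet(W, code, C, sc, sp):
    lam_u = 1.0 / (sc * sc)
    lam_v = 1.0 / (sp * sp)
    Dv = W + lam_v
    Wt = W - W * W / Dv
    S_uu = np.bincount(code, weights=Wt, minlength=C) + lam_u
    return float(np.sum(np.log(Dv)) + np.sum(np.log(S_uu)))


def fit_binomial(
    X: np.ndarray,
    columns: list[str],
    events: np.ndarray,
    n: np.ndarray,
    cluster_code: np.ndarray,
    fix_theta: tuple[float, float] | None = None,
) -> FittedModel:
    """Laplace-approximate ML fit of the two-component logistic GLMM.

    ``events``/``n`` are per-cell event counts and sizes; the cell index
    doubles as the cluster-by-period random-effect index.
    """
    X = np.asarray(X, float)
    yk = np.asarray(events, float)
    n = np.asarray(n, float)
    code = np.asarray(cluster_code)
    C = int(code.max()) + 1
    M, p = X.shape

    state = {
        "beta": np.zeros(p),
        "u": np.zeros(C),
        "v": np.zeros(M),
    }
    p0 = np.clip(yk.sum() / n.sum(), 1e-6, 1 - 1e-6)
    state["beta"][columns.index("intercept")] = float(np.log(p0 / (1 - p0)))

    def neg_laplace(x):
        sc, sp = np.maximum(np.abs(x), _SD_FLOOR)
        beta, u, v, f_pen, W, gnorm = _binomial_inner(
            state["beta"].copy(), state["u"].copy(), state["v"].copy(),
            X, yk, n, code, C, sc, sp,
        )
        state.update(beta=beta, u=u, v=v)
        logdet = _laplace_logdet(W, code, C, sc, sp)
        ll = f_pen - 0.5 * (C * np.log(sc * sc) + M * np.log(sp * sp)) - 0.5 * logdet
        state["gnorm"] = gnorm
        return -ll

    if fix_theta is not None:
        x_hat = np.maximum(np.asarray(fix_theta, float), _SD_FLOOR)
        nll = neg_laplace(x_hat)
        ok = True
        nit = 0
    else:
        res = minimize(
            neg_laplace,
            x0=np.array([0.3, 0.15]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 200},
        )
        x_hat = np.maximum(np.abs(res.x), _SD_FLOOR)
        nll = neg_laplace(x_hat)
        ok = bool(res.success)
        nit = int(res.nit)

    sc, sp = float(x_hat[0]), float(x_hat[1])
    beta, u, v = state["beta"], state["u"], state["v"]
    eta = np.clip(X @ beta + u[code] + v, -30, 30)
    mu = n * expit(eta)
    W = n * expit(eta) * (1.0 - expit(eta))

    # model-based covariance: Schur complement of the joint Hessian onto beta
    lam_u, lam_v = 1.0 / (sc * sc), 1.0 / (sp * sp)
    Dv = W + lam_v
    Wt = W - W * W / Dv
    XW = X * Wt[:, None]
    S_bb = X.T @ XW
    S_bu = _cluster_sums(code, XW, C).T
    S_uu = np.bincount(code, weights=Wt, minlength=C) + lam_u
    A = S_bb - (S_bu / S_uu) @ S_bu.T
    try:
        cov_model = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise EstimationError("singular information matrix")

    # cluster-robust sandwich from per-cluster profile scores
    resid = yk - mu
    G = _cluster_sums(code, X * resid[:, None], C)
    Gc = G - G.mean(axis=0)
    # small-sample factor G/(G-p): all fixed effects are cluster-level here
    B = Gc.T @ Gc * (C / max(C - p, 1))
    cov_robust = cov_model @ B @ cov_model

    separation = bool(np.any(np.abs(eta) > 25))
    return FittedModel(
        family="binomial_logit",
        beta=beta,
        columns=list(columns),
        cov_model=cov_model,
        cov_robust=cov_robust,
        sigma_cluster=sc,
        sigma_cluster_period=sp,
        sigma_resid=None,
        loglik=-float(nll),
        converged=ok and np.isfinite(nll),
        boundary={
            "sigma_cluster": sc <= 10 * _SD_FLOOR,
            "sigma_cluster_period": sp <= 10 * _SD_FLOOR,
            "separation": separation,
        },
        n_clusters=C,
        n_obs=int(n.sum()),
        diagnostics={
            "outer_iterations": nit,
            "inner_gradient_norm": float(state.get("gnorm", np.nan)),
            "random_effects_u": u,
            "random_effects_v": v,
        },
    )
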