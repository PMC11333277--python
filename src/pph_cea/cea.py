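"""Decision outputs: ICERs, dominance, CEACs, thresholds, DSA, budget impact.

Sign convention: incremental effects are stored as *averted* quantities
(positive = health gain), so an intervention that costs more and averts more
has a positive ICER in the conventional orientation; negative incremental
cost with positive health gain is "dominant", the reverse "dominated".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import costs as costs_mod
from . import daly as daly_mod
from .design import build_design, fit_design
from .inference import adjusted_mean_difference, marginal_risk_difference, permutation_ci
from .records import AdjustedEstimate


@dataclass(frozen=True)
class IcerResult:
    delta_cost: float
    delta_effect: float  # averted units (positive = health gain)
    icer: float | None
    status: str  # icer | dominant | dominated | undefined

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "status": self.status,
        }


def icer(delta_cost: float, delta_effect: float) -> IcerResult:
    """Incremental cost-effectiveness ratio with dominance classification.

    ``delta_effect`` is the health gain (cases or DALYs averted).
    """
    if not (np.isfinite(delta_cost) and np.isfinite(delta_effect)):
        raise ValueError("ICER inputs must be finite")
    if delta_effect == 0.0:
        return IcerResult(delta_cost, delta_effect, None, "undefined")
    if delta_cost < 0 and delta_effect > 0:
        return IcerResult(delta_cost, delta_effect, None, "dominant")
    if delta_cost > 0 and delta_effect < 0:
        return IcerResult(delta_cost, delta_effect, None, "dominated")
    return IcerResult(delta_cost, delta_effect, float(delta_cost / delta_effect), "icer")


def nmb(delta_cost: float, delta_effect: float, lam: float) -> float:
    """Net monetary benefit lambda x effect - cost at willingness-to-pay lambda."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return lam * delta_effect - delta_cost


# --------------------------------------------------------------------------
# willingness-to-pay thresholds
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WtpThresholds:
    gdp_per_capita: dict
    gdp_based: dict  # per country, 1 x GDP pc
    opportunity_cost_based: dict  # per country, share x GDP pc
    weights: dict
    weighted_gdp: float
    weighted_opportunity_cost: float

    def to_dict(self) -> dict:
        return {
            "gdp_per_capita": self.gdp_per_capita,
            "gdp_based": self.gdp_based,
            "opportunity_cost_based": self.opportunity_cost_based,
            "weights": self.weights,
            "weighted_gdp": self.weighted_gdp,
            "weighted_opportunity_cost": self.weighted_opportunity_cost,
        }


def load_threshold_config(path=None) -> dict:
    p = path if path is not None else resources.files("pph_cea").joinpath("data", "thresholds.yaml")
    with open(p) as fh:
        return yaml.safe_load(fh)


def wtp_thresholds(
    gdp_per_capita: dict[str, float],
    shares: dict[str, float],
    weights: dict[str, float],
) -> WtpThresholds:
    """Country GDP-based and opportunity-cost thresholds plus weighted versions."""
    for c in gdp_per_capita:
        if c not in shares:
            raise costs_mod.ConfigError(f"no opportunity-cost share for {c!r}")
        if gdp_per_capita[c] <= 0:
            raise ValueError("GDP per capita must be positive")
    wsum = sum(weights.get(c, 0.0) for c in gdp_per_capita)
    if wsum <= 0:
        raise ValueError("weights must have positive sum")
    wn = {c: weights.get(c, 0.0) / wsum for c in gdp_per_capita}
    gdp_based = {c: float(g) for c, g in gdp_per_capita.items()}
    opp = {c: shares[c] * g for c, g in gdp_per_capita.items()}
    return WtpThresholds(
        gdp_per_capita=dict(gdp_per_capita),
        gdp_based=gdp_based,
        opportunity_cost_based=opp,
        weights=wn,
        weighted_gdp=float(sum(wn[c] * gdp_based[c] for c in gdp_based)),
        weighted_opportunity_cost=float(sum(wn[c] * opp[c] for c in opp)),
    )


def default_thresholds() -> WtpThresholds:
    cfg = load_threshold_config()
    return wtp_thresholds(cfg["gdp_per_capita_usd"], cfg["opportunity_cost_share"], cfg["weights"])


# --------------------------------------------------------------------------
# clustered bootstrap and CEAC
# --------------------------------------------------------------------------


def cluster_bootstrap(
    records: pd.DataFrame,
    clusters: pd.DataFrame,
    cost_values: pd.Series,
    daly_values: pd.Series,
    B: int = 1000,
    seed: int = 0,
    identity: bool = False,
) -> pd.DataFrame:
    """Paired incremental (cost, DALY) estimates from a clustered bootstrap.

    Clusters are resampled with replacement within country x arm strata (a
    resampled cluster carries all its records from both phases); both
    Gaussian mixed models are re-fitted on each replicate and the paired
    treatment coefficients recorded.  ``identity=True`` disables resampling
    (each replicate reproduces the point estimates).
    """
    from .design import design_from_cells

    rng = np.random.default_rng(seed)
    d_cost0 = build_design(records, clusters, "total_cost", values=cost_values)
    d_daly0 = build_design(records, clusters, "dalys", values=daly_values)
    cost_cells = {cid: blk for cid, blk in d_cost0.cells.groupby("cluster_id")}
    daly_cells = {cid: blk for cid, blk in d_daly0.cells.groupby("cluster_id")}
    strata = [grp["cluster_id"].tolist() for _, grp in clusters.groupby(["country", "arm"])]
    for s in strata:
        if len(s) < 2 and not identity:
            raise ValueError("need >= 2 clusters per country x arm stratum to bootstrap")
    meta = clusters.set_index("cluster_id")

    out = []
    dropped = 0
    for b in range(B):
        rows_c, rows_d, cl_rows = [], [], []
        k = 0
        for s in strata:
            chosen = s if identity else list(rng.choice(s, size=len(s), replace=True))
            for cid in chosen:
                new_id = f"{cid}#{k}"
                k += 1
                bc = cost_cells[cid].copy()
                bc["cluster_id"] = new_id
                rows_c.append(bc)
                bd = daly_cells[cid].copy()
                bd["cluster_id"] = new_id
                rows_d.append(bd)
                row = meta.loc[cid].to_dict()
                row["cluster_id"] = new_id
                cl_rows.append(row)
        cl_b = pd.DataFrame(cl_rows)
        try:
            dc = fit_design(design_from_cells(pd.concat(rows_c, ignore_index=True), cl_b, "total_cost")).coef("treat")
            dd = fit_design(design_from_cells(pd.concat(rows_d, ignore_index=True), cl_b, "dalys")).coef("treat")
            out.append((dc, dd))
        except Exception:
            dropped += 1
    pairs = pd.DataFrame(out, columns=["delta_cost", "delta_daly"])
    pairs.attrs["dropped"] = dropped
    pairs.attrs["seed"] = seed
    if B > 0 and dropped / B > 0.05:
        pairs.attrs["warning"] = f"{dropped}/{B} bootstrap replicates failed"
    return pairs


@dataclass(frozen=True)
class CeacCurve:
    lam: tuple[float, ...]
    probability: tuple[float, ...]
    n_bootstrap: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda_usd_per_daly": self.lam, "probability_cost_effective": self.probability})

    def at(self, lam_value: float) -> float:
        i = int(np.argmin(np.abs(np.asarray(self.lam) - lam_value)))
        return self.probability[i]


def default_lambda_grid() -> np.ndarray:
    return np.arange(0.0, 5000.0 + 1e-9, 25.0)


def ceac(pairs: pd.DataFrame, lambda_grid=None, seed: int | None = None) -> CeacCurve:
    """Probability that the intervention is cost-effective across WTP values.

    At each lambda the probability is the fraction of bootstrap pairs with
    positive net monetary benefit (DALYs averted valued at lambda).
    """
    if len(pairs) == 0:
        raise ValueError("CEAC needs at least one bootstrap pair")
    grid = np.asarray(lambda_grid if lambda_grid is not None else default_lambda_grid(), float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("lambda grid must be strictly increasing")
    dc = pairs["delta_cost"].to_numpy()
    de = -pairs["delta_daly"].to_numpy()  # averted DALYs
    prob = [(grid_v * de - dc > 0).mean() for grid_v in grid]
    return CeacCurve(lam=tuple(grid), probability=tuple(map(float, prob)), n_bootstrap=len(pairs), seed=seed)


# --------------------------------------------------------------------------
# deterministic sensitivity analysis, country CUAs, budget impact
# --------------------------------------------------------------------------

DSA_DRAPE_PRICES_2023 = (1.00, 0.75, 0.50)


def dsa_drape_price(
    records: pd.DataFrame,
    clusters: pd.DataFrame,
    daly_estimate: AdjustedEstimate,
    prices=DSA_DRAPE_PRICES_2023,
    base_price: float | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-run the cost analysis at alternative drape device prices (2023 USD).

    Currency adjustment and the traded-good markup are re-applied per price;
    the DALY model is untouched (drape price cannot enter DALYs), so its row
    is constant.  Returns a table with one row per price.
    """
    rows = []
    price_list = list(prices) if base_price is None else [base_price, *prices]
    for price in price_list:
        table = costs_mod.default_unit_cost_table(drape_price_2023=price)
        cost_vals = costs_mod.patient_cost(records, table)
        d_cost = build_design(records, clusters, "total_cost", values=cost_vals)
        m_cost = fit_design(d_cost)
        est = permutation_ci(d_cost, clusters, model=m_cost, n_perm=n_perm, seed=seed)
        res = icer(est.point, -daly_estimate.point)
        rows.append(
            dict(
                drape_price_2023=price,
                delta_cost=est.point,
                delta_cost_ci_low=est.ci_low,
                delta_cost_ci_high=est.ci_high,
                delta_daly=daly_estimate.point,
                icer_per_daly=res.icer,
                status=res.status,
            )
        )
    return pd.DataFrame(rows)


def pooled_one_country_cua(
    records: pd.DataFrame,
    clusters: pd.DataFrame,
    country: str,
    unit_costs: costs_mod.UnitCostTable,
    life_tables: dict,
    daly_params: daly_mod.DalyParams,
    thresholds: WtpThresholds,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """Fully pooled one-country costing CUA.

    All patients are re-costed with ``country``'s unit costs and re-DALYed
    with its life table; models are re-fitted with the main adjustment set
    and the ICER judged against that country's thresholds.
    """
    one_costs = costs_mod.single_country_table(unit_costs, country)
    cost_vals = costs_mod.patient_cost(records, one_costs)
    lt = {c: life_tables[country] for c in set(records["country"])}
    daly_vals = daly_mod.attach_dalys(records, daly_params, lt)

    d_cost = build_design(records, clusters, "total_cost", values=cost_vals)
    d_daly = build_design(records, clusters, "dalys", values=daly_vals)
    m_cost, m_daly = fit_design(d_cost), fit_design(d_daly)
    est_cost = permutation_ci(d_cost, clusters, model=m_cost, n_perm=n_perm, seed=seed)
    est_daly = permutation_ci(d_daly, clusters, model=m_daly, n_perm=n_perm, seed=seed + 1)
    res = icer(est_cost.point, -est_daly.point)
    return {
        "country": country,
        "delta_cost": est_cost.to_dict(),
        "delta_daly": est_daly.to_dict(),
        "icer": res.to_dict(),
        "gdp_threshold": thresholds.gdp_based[country],
        "opportunity_cost_threshold": thresholds.opportunity_cost_based[country],
        "cost_effective_gdp": _cost_effective(res, thresholds.gdp_based[country]),
        "cost_effective_opportunity_cost": _cost_effective(res, thresholds.opportunity_cost_based[country]),
    }


def _cost_effective(res: IcerResult, lam: float) -> bool | None:
    if res.status == "dominant":
        return True
    if res.status == "dominated":
        return False
    if res.status == "undefined":
        return None
    return bool(res.icer <= lam) if res.delta_effect > 0 else bool(res.icer > lam)


def budget_impact(delta_cost_per_birth: float, annual_births_by_country: dict[str, float]) -> dict:
    """Annual incremental expenditure at service volume: dC x annual births."""
    per_country = {c: float(delta_cost_per_birth) * float(n) for c, n in annual_births_by_country.items()}
    return {"per_country": per_country, "total": float(sum(per_country.values()))}
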