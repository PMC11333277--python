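"""End-to-end orchestration of the economic evaluation.

Stages: load/generate records -> complete-case accounting -> DALYs -> costs
-> adjusted models (marginal risk difference; permutation CIs for cost and
DALY differences) -> clustered bootstrap and CEAC -> ICERs vs thresholds ->
drape-price DSA -> optional country-level CUAs, budget impact and
multiple-imputation sensitivity.  Every artifact is stamped with the config
hash, master seed and package version; a run log records per-stage record
counts and exclusions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cea as cea_mod
from . import costs as costs_mod
from . import daly as daly_mod
from .design import build_design, fit_design
from .inference import adjusted_mean_difference, impute_and_pool, marginal_risk_difference, permutation_ci
from .records import complete_case_split, read_birth_records, read_clusters
from .reports import CeaReport, summarize, write_report
from .synth import TrialScenario, default_scenario, generate_trial

log = logging.getLogger("pph_cea")


@dataclass
class RunConfig:
    """Configuration for one full analysis run."""

    records_path: str | None = None
    clusters_path: str | None = None
    scenario: dict | None = None  # synthetic scenario overrides; {} = defaults
    use_multiple_imputation: bool = False
    m_imputations: int = 7
    n_perm: int = 1000
    n_bootstrap: int = 1000
    lambda_max: float = 5000.0
    lambda_step: float = 25.0
    dsa_prices: tuple = cea_mod.DSA_DRAPE_PRICES_2023
    country_level: bool = True
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        file_input = self.records_path is not None
        if file_input == (self.scenario is not None):
            raise ValueError("exactly one of records_path/clusters_path or scenario must be set")
        if min(self.n_perm, self.n_bootstrap, self.m_imputations) <= 0:
            raise ValueError("replication counts must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "dsa_prices" in raw:
            raw["dsa_prices"] = tuple(raw["dsa_prices"])
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("output_dir")  # where artifacts land does not affect the analysis
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds spawned from the master seed (< 2^31)."""
    ss = np.random.SeedSequence(int(master_seed))
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _group_summary(records: pd.DataFrame, values: dict[str, pd.Series]) -> dict:
    out = {}
    for phase in ("baseline", "implementation"):
        for arm in ("intervention", "usual_care"):
            m = (records["phase"] == phase) & (records["arm"] == arm)
            sub = records.loc[m]
            sev = (sub["blood_loss_ml"] >= 1000.0).mean() if len(sub) else float("nan")
            entry = {"n": int(m.sum()), "severe_pph_rate": float(sev)}
            for name, series in values.items():
                vals = series.loc[sub.index]
                entry[f"mean_{name}"] = float(vals.mean())
                entry[f"sd_{name}"] = float(vals.std())
            out[f"{arm}/{phase}"] = entry
    return out


def run(config: RunConfig) -> CeaReport:
    """Execute the full analysis; returns the report and writes artifacts."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    cfg_hash = config.config_hash()

    # --- stage: data ---------------------------------------------------------
    if config.scenario is not None:
        scenario = TrialScenario(**{**default_scenario().to_dict(), **config.scenario, "seed": seeds[0]})
        clusters, records = generate_trial(scenario)
        log.info("generated synthetic trial: %d clusters, %d records", len(clusters), len(records))
    else:
        records = read_birth_records(config.records_path)
        clusters = read_clusters(config.clusters_path)
        log.info("loaded %d records across %d clusters", len(records), len(clusters))

    # fail fast on configuration gaps before heavy computation
    unit_costs = costs_mod.default_unit_cost_table()
    life_tables = daly_mod.load_life_tables(costs_mod._data_path("life_tables.csv"))
    thresholds = cea_mod.default_thresholds()
    daly_params = daly_mod.DalyParams()

    cc, excluded = complete_case_split(records)
    accounting = {
        "n_input": len(records),
        "n_analysed": len(cc),
        "n_excluded_missing_blood_loss": len(excluded),
        "follow_up_pct": 100.0 * len(cc) / len(records) if len(records) else float("nan"),
    }
    assert accounting["n_analysed"] + accounting["n_excluded_missing_blood_loss"] == accounting["n_input"]
    log.info("complete-case accounting: %s", accounting)

    # --- stage: outcomes -----------------------------------------------------
    cost_vals = costs_mod.patient_cost(cc, unit_costs)
    daly_vals = daly_mod.attach_dalys(cc, daly_params, life_tables)

    report = CeaReport(
        meta={
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": seeds,
            "config_hash": cfg_hash,
            "synthetic": config.scenario is not None,
        },
        accounting=accounting,
        group_summaries=_group_summary(cc, {"cost": cost_vals, "dalys": daly_vals}),
    )

    # --- stage: adjusted models ----------------------------------------------
    d_sev = build_design(cc, clusters, "severe_pph")
    m_sev = fit_design(d_sev)
    rd = marginal_risk_difference(m_sev, d_sev)

    d_cost = build_design(cc, clusters, "total_cost", values=cost_vals)
    m_cost = fit_design(d_cost)
    est_cost = permutation_ci(d_cost, clusters, model=m_cost, n_perm=config.n_perm, seed=seeds[1])

    d_daly = build_design(cc, clusters, "dalys", values=daly_vals)
    m_daly = fit_design(d_daly)
    est_daly = permutation_ci(d_daly, clusters, model=m_daly, n_perm=config.n_perm, seed=seeds[2])

    report.adjusted = {
        "risk_difference_pp": rd.to_dict(),
        "cost_difference_usd": est_cost.to_dict(),
        "daly_difference": est_daly.to_dict(),
        "models": {
            "severe_pph": m_sev.to_dict(),
            "total_cost": {k: v for k, v in m_cost.to_dict().items() if k != "coefficients"},
            "dalys": {k: v for k, v in m_daly.to_dict().items() if k != "coefficients"},
        },
    }
    log.info("adjusted RD %.3f pp; cost diff %.3f USD; DALY diff %.5f", rd.point, est_cost.point, est_daly.point)

    # --- stage: ICERs & thresholds -------------------------------------------
    icer_sev = cea_mod.icer(est_cost.point, -rd.point / 100.0)  # cases averted per birth
    icer_daly = cea_mod.icer(est_cost.point, -est_daly.point)
    report.icers = {
        "per_severe_pph_averted": icer_sev.to_dict(),
        "per_daly_averted": icer_daly.to_dict(),
    }
    report.thresholds = thresholds.to_dict()

    # --- stage: bootstrap + CEAC ---------------------------------------------
    pairs = cea_mod.cluster_bootstrap(
        cc, clusters, cost_vals, daly_vals, B=config.n_bootstrap, seed=seeds[3]
    )
    grid = np.arange(0.0, config.lambda_max + 1e-9, config.lambda_step)
    curve = cea_mod.ceac(pairs, grid, seed=seeds[3])
    report.ceac = [[float(l), float(p)] for l, p in zip(curve.lam, curve.probability)]
    curve.to_frame().to_csv(outdir / "ceac.csv", index=False)
    _plot_ceac(curve, thresholds, outdir / "ceac.png")
    pairs.to_csv(outdir / "bootstrap_pairs.csv", index=False)

    # --- stage: DSA ------------------------------------------------------------
    dsa = cea_mod.dsa_drape_price(
        cc, clusters, est_daly, prices=config.dsa_prices, n_perm=config.n_perm, seed=seeds[4]
    )
    report.dsa = dsa.to_dict(orient="records")
    dsa.to_csv(outdir / "dsa_drape_price.csv", index=False)

    # --- stage: country level + budget impact ---------------------------------
    if config.country_level:
        report.country_level = {
            country: cea_mod.pooled_one_country_cua(
                cc, clusters, country, unit_costs, life_tables, daly_params, thresholds,
                n_perm=min(config.n_perm, 200), seed=seeds[5] + i,
            )
            for i, country in enumerate(sorted(set(clusters["country"])))
        }
    births = clusters.groupby("country")["annual_vaginal_births"].sum().to_dict()
    report.budget_impact = cea_mod.budget_impact(est_cost.point, births)

    # --- stage: multiple-imputation sensitivity -------------------------------
    if config.use_multiple_imputation and len(excluded):
        mi_rd = impute_and_pool(records, clusters, "severe_pph", m=config.m_imputations, seed=seeds[6])
        mi_daly = impute_and_pool(
            records, clusters, "dalys",
            value_fn=lambda df: daly_mod.attach_dalys(df, daly_params, life_tables),
            m=config.m_imputations, seed=seeds[6] + 1,
        )
        report.sensitivity["multiple_imputation"] = {
            "risk_difference_pp": mi_rd.to_dict(),
            "daly_difference": mi_daly.to_dict(),
        }

    report.meta["runtime_s"] = round(time.time() - t0, 2)
    write_report(report, outdir / "report.json")
    (outdir / "summary.txt").write_text(summarize(report) + "\n")
    log.info("run complete in %.1fs; artifacts in %s", time.time() - t0, outdir)
    return report


def _plot_ceac(curve, thresholds, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.lam, curve.probability, lw=2)
    ax.axvline(thresholds.weighted_gdp, color="green", ls="--", lw=1, label="GDP-based threshold")
    ax.axvline(thresholds.weighted_opportunity_cost, color="blue", ls="--", lw=1, label="opportunity-cost threshold")
    ax.set_xlabel("Willingness to pay per DALY averted (2022 USD)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
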