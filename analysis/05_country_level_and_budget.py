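#!/usr/bin/env python
"""Country-level perspective: fully pooled one-country costing CUAs + budget impact.

Clinical data from all countries are pooled; each country's unit costs and
life table are applied to every patient, models re-fitted with the main
adjustment set, and ICERs judged against the country's own GDP-based and
opportunity-cost thresholds.  The budget impact extrapolates the adjusted
per-birth cost difference to annual vaginal-birth volumes.
"""

import json
from pathlib import Path

from pph_cea import costs as costs_mod
from pph_cea import daly as daly_mod
from pph_cea.cea import budget_impact, default_thresholds, pooled_one_country_cua
from pph_cea.design import build_design
from pph_cea.inference import permutation_ci
from pph_cea.synth import default_scenario, generate_trial

SEED = 1
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    clusters, records = generate_trial(default_scenario(seed=SEED))
    cc = records[records["blood_loss_ml"].notna()]
    table = costs_mod.default_unit_cost_table()
    life_tables = daly_mod.load_life_tables(costs_mod._data_path("life_tables.csv"))
    params = daly_mod.DalyParams()
    thr = default_thresholds()

    out = {}
    for i, country in enumerate(sorted(set(clusters["country"]))):
        res = pooled_one_country_cua(
            cc, clusters, country, table, life_tables, params, thr, n_perm=200, seed=SEED + 20 + i
        )
        out[country] = res
        status = res["icer"]["status"]
        shown = f"{res['icer']['icer']:.2f} USD/DALY" if status == "icer" else status
        print(
            f"{country:13s} ICER {shown:>18s} | thresholds {res['opportunity_cost_threshold']:.0f}/"
            f"{res['gdp_threshold']:.0f} USD | cost-effective (opp. cost): {res['cost_effective_opportunity_cost']}"
        )

    cost = costs_mod.patient_cost(cc, table)
    d_cost = build_design(cc, clusters, "total_cost", values=cost)
    est_cost = permutation_ci(d_cost, clusters, n_perm=200, seed=SEED + 1)
    births = clusters.groupby("country")["annual_vaginal_births"].sum().to_dict()
    bi = budget_impact(est_cost.point, births)
    out["budget_impact"] = bi
    print(f"\nannual budget impact at dC {est_cost.point:+.2f} USD/birth:")
    for c, v in bi["per_country"].items():
        print(f"  {c:13s} {v:+12,.0f} USD/year ({births[c]:,} births)")
    print(f"  {'total':13s} {bi['total']:+12,.0f} USD/year")

    (RESULTS / "05_country_level.json").write_text(json.dumps(out, indent=2, default=float))


if __name__ == "__main__":
    main()
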