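"""Unit-cost assembly and per-patient healthcare-system costing (2022 USD).

The costing pipeline per item is: convert the raw price to USD at the
price-year exchange rate, inflate to 2022 with the average US inflation rate,
add a 25% markup for shipping/handling/internal distribution of traded goods,
transfer prices to countries without data via a market-basket index of
relative inpatient/outpatient service-delivery costs, and finally apply the
derivation rules for items costed indirectly (postpartum laparotomy = 80% of
a hysterectomy; manual procedures and physician attendance from the
per-minute rate of the lowest-grade doctor who could attend a severe PPH;
uterine massage and examination costed at zero as reprioritized staff time).

Per-patient cost is the inner product of resource-use quantities with the
country's unit costs; trial follow-up is short, so costs are not discounted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .records import COUNTRIES, RESOURCE_ITEMS

TRADE_MARKUP = 0.25
PRICE_YEAR_TARGET = 2022


class ConfigError(ValueError):
    """A costing configuration gap (missing fx/CPI entry, unpriced item, ...)."""


def _data_path(name: str):
    return resources.files("pph_cea").joinpath("data", name)


def load_fx_table(path=None) -> dict[tuple[str, int], float]:
    df = pd.read_csv(path if path is not None else _data_path("fx_rates.csv"))
    return {(str(r.currency), int(r.year)): float(r.units_per_usd) for r in df.itertuples()}


def load_cpi_table(path=None) -> dict[int, float]:
    df = pd.read_csv(path if path is not None else _data_path("us_cpi.csv"))
    return {int(r.year): float(r.factor_to_2022) for r in df.itertuples()}


def load_market_basket(path=None) -> dict[str, float]:
    df = pd.read_csv(path if path is not None else _data_path("market_basket.csv"))
    index = {str(r.country): float(r.index) for r in df.itertuples()}
    if any(v <= 0 for v in index.values()):
        raise ConfigError("market-basket indices must be positive")
    return index


def load_raw_unit_costs(path=None) -> pd.DataFrame:
    df = pd.read_csv(path if path is not None else _data_path("unit_costs.csv"))
    df["traded_good"] = df["traded_good"].astype(str).str.lower().isin(["true", "1", "yes"])
    if (df["amount"] < 0).any():
        raise ConfigError("raw unit costs must be non-negative")
    bad_year = ~df["price_year"].between(1990, 2023)
    if bad_year.any():
        raise ConfigError(f"implausible price_year rows: {list(df.index[bad_year])}")
    return df


def load_derivation_rules(path=None) -> dict:
    p = path if path is not None else _data_path("derivation_rules.yaml")
    with open(p) as fh:
        return yaml.safe_load(fh)


def adjust_to_usd_2022(amount: float, currency: str, price_year: int, fx_table, cpi_table) -> float:
    """Convert at price-year exchange rate, then inflate with US CPI to 2022."""
    price_year = int(price_year)
    if currency == "USD" and price_year == PRICE_YEAR_TARGET:
        return float(amount)
    key = (currency, price_year)
    if currency == "USD":
        fx = 1.0
    elif key in fx_table:
        fx = fx_table[key]
    else:
        raise ConfigError(f"no exchange rate for {currency} in {price_year}")
    if price_year not in cpi_table:
        raise ConfigError(f"no US CPI factor for {price_year}")
    return float(amount) / fx * cpi_table[price_year]


def apply_trade_markup(cost: float, traded_good: bool, markup: float = TRADE_MARKUP) -> float:
    """25% shipping/handling/distribution markup on traded goods only."""
    if cost < 0:
        raise ValueError("cost must be non-negative")
    return cost * (1.0 + markup) if traded_good else cost


def market_basket_transfer(cost: float, from_country: str, to_country: str, index: dict[str, float]) -> float:
    """Transfer a unit cost between countries in proportion to the basket index."""
    for c in (from_country, to_country):
        if c not in index:
            raise ConfigError(f"country {c!r} missing from market-basket index")
    return cost * index[to_country] / index[from_country]


@dataclass(frozen=True)
class UnitCostTable:
    """Completed (country x item) unit costs in 2022 USD."""

    table: pd.DataFrame  # index: country, columns: items
    provenance: dict

    def cost(self, country: str, item: str) -> float:
        try:
            return float(self.table.loc[country, item])
        except KeyError as exc:
            raise ConfigError(f"no unit cost for ({country!r}, {item!r})") from exc

    def complete_for(self, items=RESOURCE_ITEMS, countries=COUNTRIES) -> bool:
        sub = self.table.reindex(index=countries, columns=items)
        return not sub.isna().any().any()

    def to_raw(self) -> pd.DataFrame:
        """Express the completed table as raw 2022-USD rows (for rebuild/round-trip)."""
        rows = []
        for country in self.table.index:
            for item in self.table.columns:
                rows.append(
                    dict(
                        item=item,
                        country=country,
                        amount=float(self.table.loc[country, item]),
                        currency="USD",
                        price_year=PRICE_YEAR_TARGET,
                        traded_good=False,
                        source_tag="derived: completed table",
                    )
                )
        return pd.DataFrame(rows)


def build_unit_cost_table(
    raw: pd.DataFrame,
    basket_index: dict[str, float] | None = None,
    fx_table=None,
    cpi_table=None,
    rules: dict | None = None,
    countries=COUNTRIES,
    markup: float = TRADE_MARKUP,
) -> UnitCostTable:
    """Assemble the complete per-country unit-cost table from raw prices.

    Pipeline: currency/inflation adjustment -> traded-good markup ->
    market-basket fill of missing countries -> derivation rules.
    """
    basket_index = basket_index if basket_index is not None else load_market_basket()
    fx_table = fx_table if fx_table is not None else load_fx_table()
    cpi_table = cpi_table if cpi_table is not None else load_cpi_table()
    rules = rules if rules is not None else load_derivation_rules()

    direct_items = sorted(set(raw["item"]))
    table = pd.DataFrame(np.nan, index=list(countries), columns=direct_items, dtype=float)
    for r in raw.itertuples():
        usd = adjust_to_usd_2022(r.amount, r.currency, r.price_year, fx_table, cpi_table)
        usd = apply_trade_markup(usd, bool(r.traded_good), markup)
        targets = list(countries) if r.country == "any" else [r.country]
        for c in targets:
            table.loc[c, r.item] = usd

    # market-basket transfer to fill countries with no direct price
    for item in direct_items:
        col = table[item]
        if col.isna().all():
            raise ConfigError(f"item {item!r} has no price in any country")
        if col.isna().any():
            donor = col.dropna().index[0]
            for c in col.index[col.isna()]:
                table.loc[c, item] = market_basket_transfer(col[donor], donor, c, basket_index)

    # derived items
    for item, rule in rules.items():
        kind = rule["rule"] if isinstance(rule, dict) else rule
        if kind == "zero":
            table[item] = 0.0
        elif kind == "fraction_of":
            src = rule["of"]
            if src not in table.columns:
                raise ConfigError(f"derivation of {item!r} needs unpriced item {src!r}")
            table[item] = rule["factor"] * table[src]
        elif kind == "personnel_per_min":
            if "personnel_min" not in table.columns:
                raise ConfigError(f"derivation of {item!r} needs 'personnel_min' rates")
            table[item] = table["personnel_min"]
        else:
            raise ConfigError(f"unknown derivation rule {kind!r} for {item!r}")

    missing = [i for i in RESOURCE_ITEMS if i not in table.columns or table[i].isna().any()]
    if missing:
        raise ConfigError(f"unit-cost table incomplete for items: {missing}")
    prov = {"markup": markup, "n_raw": len(raw)}
    return UnitCostTable(table=table, provenance=prov)


def default_unit_cost_table(drape_price_2023: float | None = None) -> UnitCostTable:
    """Packaged synthetic default table; optionally override the drape device price.

    ``drape_price_2023`` is the raw device price per unit in 2023 USD, before
    the 2022 adjustment and the traded-good markup (the deterministic
    sensitivity analysis varies exactly this number).
    """
    raw = load_raw_unit_costs()
    if drape_price_2023 is not None:
        raw.loc[raw["item"] == "calibrated_drape", "amount"] = float(drape_price_2023)
    return build_unit_cost_table(raw)


def single_country_table(table: UnitCostTable, country: str) -> UnitCostTable:
    """Apply one country's unit costs to every analysis country (pooled one-country costing)."""
    if country not in table.table.index:
        raise ConfigError(f"country {country!r} not in unit-cost table")
    row = table.table.loc[country]
    new = pd.DataFrame([row.to_numpy()] * len(table.table.index), index=table.table.index, columns=table.table.columns)
    return UnitCostTable(table=new, provenance={**table.provenance, "one_country": country})


def patient_cost(records: pd.DataFrame, table: UnitCostTable, with_components: bool = False):
    """Total per-patient cost (2022 USD): sum of quantity x country unit cost.

    Vectorized over a validated record frame.  With ``with_components`` the
    per-item cost matrix is returned alongside; it sums row-wise to the total.
    """
    missing = [i for i in RESOURCE_ITEMS if i not in table.table.columns]
    if missing:
        raise ConfigError(f"resource categories missing from unit-cost table: {missing}")
    cost_mat = table.table.reindex(index=records["country"], columns=RESOURCE_ITEMS)
    if cost_mat.isna().any().any():
        bad = sorted(set(records["country"]) - set(table.table.index))
        raise ConfigError(f"unit-cost table incomplete for countries: {bad}")
    q = records[RESOURCE_ITEMS].to_numpy(dtype=float)
    comp = q * cost_mat.to_numpy(dtype=float)
    total = pd.Series(comp.sum(axis=1), index=records.index, name="total_cost")
    if with_components:
        comp_df = pd.DataFrame(comp, index=records.index, columns=RESOURCE_ITEMS)
        return total, comp_df
    return total
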