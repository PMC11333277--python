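"""DALY computation for PPH outcomes.

Disability-adjusted life-years combine years lived with disability (YLD) for
nonfatal PPH and discounted years of life lost (YLL) for maternal death from
bleeding.  Disability weights follow the Global Burden of Disease convention:
0.324 for severe PPH (>=1,000 ml lost) and 0.114 for less severe PPH
(500-999 ml), each lasting the 6-week postpartum period.  YLL discounts the
country- and age-specific female remaining life expectancy at a 3% annual
rate using the continuous-time convention (1 - e^{-rL}) / r.

No age weighting is applied, YLD for a decedent is not added to her YLL (the
death pathway replaces morbidity over the same window), and the 6-week
morbidity duration is not itself discounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import PPH_THRESHOLD_ML, SEVERE_THRESHOLD_ML

WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class DalyParams:
    dw_severe: float = 0.324
    dw_less_severe: float = 0.114
    duration_weeks: float = 6.0
    discount_rate: float = 0.03  # per year
    severe_threshold_ml: float = SEVERE_THRESHOLD_ML
    pph_threshold_ml: float = PPH_THRESHOLD_ML

    def __post_init__(self) -> None:
        if not (0.0 <= self.dw_less_severe <= 1.0 and 0.0 <= self.dw_severe <= 1.0):
            raise ValueError("disability weights must lie in [0, 1]")
        if self.duration_weeks <= 0:
            raise ValueError("duration must be positive")
        if not (0.0 <= self.discount_rate < 1.0):
            raise ValueError("discount rate must lie in [0, 1)")


@dataclass(frozen=True)
class LifeTable:
    """Abridged female life table: remaining life expectancy at tabulated ages."""

    country: str
    ages: tuple[float, ...]
    remaining_le: tuple[float, ...]

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        le = np.asarray(self.remaining_le, dtype=float)
        if ages.size != le.size or ages.size < 2:
            raise ValueError("life table needs >= 2 (age, LE) pairs of equal length")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("life-table ages must be strictly increasing")
        if not np.all(le > 0):
            raise ValueError("remaining life expectancy must be positive")


def load_life_tables(path) -> dict[str, LifeTable]:
    """Load per-country life tables from a CSV with columns country, age_years, remaining_le."""
    df = pd.read_csv(path)
    tables = {}
    for country, grp in df.groupby("country"):
        grp = grp.sort_values("age_years")
        tables[country] = LifeTable(
            country=str(country),
            ages=tuple(grp["age_years"].astype(float)),
            remaining_le=tuple(grp["remaining_le"].astype(float)),
        )
    return tables


def yld(blood_loss_ml, params: DalyParams = DalyParams()):
    """Years lived with disability for a (nonfatal) birth with the given blood loss.

    A step function of blood loss: 0 below the PPH threshold, then
    dw_less_severe x duration, then dw_severe x duration (duration in years).
    Accepts scalars or arrays; NaN propagates.
    """
    bl = np.asarray(blood_loss_ml, dtype=float)
    if np.any(bl[~np.isnan(bl)] < 0):
        raise ValueError("blood loss must be non-negative")
    duration_years = params.duration_weeks / WEEKS_PER_YEAR
    dw = np.where(
        bl >= params.severe_threshold_ml,
        params.dw_severe,
        np.where(bl >= params.pph_threshold_ml, params.dw_less_severe, 0.0),
    )
    out = dw * duration_years
    out = np.where(np.isnan(bl), np.nan, out)
    return out if out.ndim else float(out)


def remaining_life_expectancy(age_years, table: LifeTable):
    """Linearly interpolated remaining female life expectancy at the given age."""
    age = np.asarray(age_years, dtype=float)
    lo, hi = table.ages[0], table.ages[-1]
    if np.any(age < lo) or np.any(age > hi):
        raise ValueError(f"age outside life-table span [{lo}, {hi}]")
    out = np.interp(age, table.ages, table.remaining_le)
    return out if out.ndim else float(out)


def discounted_yll(remaining_le, discount_rate: float = 0.03):
    """Discounted years of life lost for a death with the given remaining life expectancy.

    Continuous-time discounting: (1 - exp(-r L)) / r, with the r -> 0 limit L.
    """
    L = np.asarray(remaining_le, dtype=float)
    if np.any(L < 0):
        raise ValueError("remaining life expectancy must be non-negative")
    if discount_rate < 0:
        raise ValueError("discount rate must be non-negative")
    if discount_rate == 0.0:
        out = L
    else:
        out = (1.0 - np.exp(-discount_rate * L)) / discount_rate
    return out if np.ndim(out) else float(out)


def patient_dalys(
    blood_loss_ml,
    death_from_bleeding,
    age_years,
    country,
    params: DalyParams,
    life_tables: dict[str, LifeTable],
):
    """Per-patient DALYs: YLL for deaths from bleeding, YLD otherwise.

    Vectorized over records.  Survivors with missing blood loss get NaN (to be
    excluded by complete-case analysis or filled by imputation).
    """
    bl = np.asarray(blood_loss_ml, dtype=float)
    dead = np.asarray(death_from_bleeding, dtype=bool)
    age = np.asarray(age_years, dtype=float)
    country = np.asarray(country, dtype=object)

    out = np.full(bl.shape, np.nan)
    surv = ~dead
    if surv.any():
        # yld propagates NaN for survivors with unverified blood loss
        out[surv] = np.asarray(yld(bl[surv], params))

    if dead.any():
        r = params.discount_rate
        for c in np.unique(country[dead]):
            if c not in life_tables:
                raise KeyError(f"no life table for country {c!r}")
            m = dead & (country == c)
            le = remaining_life_expectancy(age[m], life_tables[c])
            out[m] = discounted_yll(le, r)
    return out


def attach_dalys(records: pd.DataFrame, params: DalyParams, life_tables: dict[str, LifeTable]) -> pd.Series:
    """DALY series aligned with a validated record frame."""
    vals = patient_dalys(
        records["blood_loss_ml"].to_numpy(),
        records["death_from_bleeding"].to_numpy(),
        records["age_years"].to_numpy(),
        records["country"].to_numpy(),
        params,
        life_tables,
    )
    return pd.Series(vals, index=records.index, name="dalys")
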