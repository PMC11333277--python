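"""Patient-level birth records and cluster metadata: schema, validation, CSV I/O.

A "birth record" is one vaginal birth in one hospital (cluster): identifiers,
trial phase and arm, measured blood loss (ml, possibly missing when not
source-verified), a death-from-bleeding flag, maternal age, and resource-use
quantities for the healthcare-system costing.

Records are held as a pandas DataFrame with the columns in :data:`RECORD_COLUMNS`
plus one column per resource category in :data:`RESOURCE_ITEMS`.  PPH flags are
always derived from blood loss (>=500 ml; severe >=1000 ml), never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COUNTRIES = ["kenya", "nigeria", "south_africa", "tanzania"]
PHASES = ["baseline", "implementation"]
ARMS = ["intervention", "usual_care"]

#: blood-loss thresholds (ml); closed lower bounds (">= 500", ">= 1000")
PPH_THRESHOLD_ML = 500.0
SEVERE_THRESHOLD_ML = 1000.0

#: resource-use categories costed from the healthcare-system perspective.
#: Quantities are counts/units/days/minutes per birth.
RESOURCE_ITEMS = [
    "calibrated_drape",
    "uterotonic_dose",
    "txa_dose",
    "iv_fluid_unit",
    "hospital_day",
    "icu_day",
    "transfer",
    "transfusion_unit",
    "laparotomy",
    "hysterectomy",
    "nasg",
    "balloon_tamponade",
    "bimanual_compression_min",
    "physician_min",
    "uterine_massage",
    "examination",
]

RECORD_COLUMNS = [
    "patient_id",
    "cluster_id",
    "country",
    "phase",
    "arm",
    "blood_loss_ml",
    "source_verified",
    "death_from_bleeding",
    "age_years",
]

CLUSTER_COLUMNS = [
    "cluster_id",
    "country",
    "arm",
    "annual_vaginal_births",
    "baseline_event_proportion",
    "oxytocin_quality",
]


class SchemaError(ValueError):
    """A mandatory column is missing or the file cannot be interpreted."""


class ValidationError(ValueError):
    """One or more rows violate a hard invariant; message lists row indices."""


@dataclass(frozen=True)
class AdjustedEstimate:
    """Adjusted between-arm difference with its confidence interval.

    ``point`` and the CI are on the outcome scale (percentage points for risk
    differences, 2022 USD for costs, DALYs for disease burden).
    """

    point: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    method: str = "model_wald"  # model_wald | permutation | bootstrap | rubin_pooled
    n_reps: int = 0
    seed: int | None = None
    se: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] must bracket point {self.point}"
            )

    def to_dict(self) -> dict:
        return {
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha": self.alpha,
            "method": self.method,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "se": self.se,
        }


def pph_flags(blood_loss_ml: pd.Series) -> pd.DataFrame:
    """Derive PPH (>=500 ml) and severe-PPH (>=1000 ml) indicator columns.

    Missing blood loss yields missing flags (pandas nullable booleans); severe
    implies PPH by construction.
    """
    bl = pd.to_numeric(blood_loss_ml, errors="coerce")
    pph = pd.Series(bl >= PPH_THRESHOLD_ML, dtype="boolean").mask(bl.isna())
    severe = pd.Series(bl >= SEVERE_THRESHOLD_ML, dtype="boolean").mask(bl.isna())
    return pd.DataFrame({"pph": pph, "severe_pph": severe})


def _check_rows(mask: pd.Series, what: str, problems: list[str]) -> None:
    if mask.any():
        rows = list(np.flatnonzero(mask.to_numpy())[:20])
        problems.append(f"{what} (rows {rows}{'...' if mask.sum() > 20 else ''})")


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a record table against the hard invariants.

    Returns the validated frame (with normalized dtypes).  Raises
    :class:`SchemaError` for missing columns and :class:`ValidationError` with
    row-indexed diagnostics for invariant violations.  Missing blood loss is
    preserved as NaN (flagged for complete-case exclusion / imputation), never
    coerced to zero.
    """
    missing = [c for c in RECORD_COLUMNS + RESOURCE_ITEMS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    df = df.copy()
    df["blood_loss_ml"] = pd.to_numeric(df["blood_loss_ml"], errors="coerce")
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    for col in ("source_verified", "death_from_bleeding"):
        if df[col].dtype == object:
            df[col] = (
                df[col].astype(str).str.strip().str.lower().map(
                    {"true": True, "false": False, "1": True, "0": False}
                )
            )
        df[col] = df[col].astype(bool)
    for col in RESOURCE_ITEMS:
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0.0)

    problems: list[str] = []
    _check_rows(df["blood_loss_ml"] < 0, "negative blood_loss_ml", problems)
    _check_rows(~df["country"].isin(COUNTRIES), "unknown country", problems)
    _check_rows(~df["phase"].isin(PHASES), "unknown phase", problems)
    _check_rows(~df["arm"].isin(ARMS), "unknown arm", problems)
    _check_rows(~(df["age_years"] > 0), "non-positive or missing age_years", problems)
    neg_res = (df[RESOURCE_ITEMS] < 0).any(axis=1)
    _check_rows(neg_res, "negative resource-use quantity", problems)
    # a record with missing blood loss cannot be source-verified
    _check_rows(
        df["blood_loss_ml"].isna() & df["source_verified"],
        "source_verified true but blood_loss_ml missing",
        problems,
    )
    if problems:
        raise ValidationError("; ".join(problems))
    return df


def validate_clusters(df: pd.DataFrame, records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate cluster metadata; optionally check referential integrity."""
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory cluster columns: {missing}")
    df = df.copy()
    problems: list[str] = []
    _check_rows(~df["country"].isin(COUNTRIES), "unknown country", problems)
    _check_rows(~df["arm"].isin(ARMS), "unknown arm", problems)
    births = pd.to_numeric(df["annual_vaginal_births"], errors="coerce")
    # hospital eligibility: 1,000-5,000 vaginal births per year
    _check_rows(~births.between(1000, 5000), "annual_vaginal_births outside [1000, 5000]", problems)
    prop = pd.to_numeric(df["baseline_event_proportion"], errors="coerce")
    _check_rows(~prop.between(0, 1), "baseline_event_proportion outside [0, 1]", problems)
    if df["cluster_id"].duplicated().any():
        problems.append("duplicate cluster_id")
    if problems:
        raise ValidationError("; ".join(problems))
    if records is not None:
        unknown = set(records["cluster_id"]) - set(df["cluster_id"])
        if unknown:
            raise ValidationError(f"records reference unknown clusters: {sorted(unknown)[:10]}")
    return df


def read_birth_records(path) -> pd.DataFrame:
    """Read and validate a birth-record CSV (UTF-8, header row, empty cell = missing)."""
    df = pd.read_csv(path)
    return validate_records(df)


def write_birth_records(df: pd.DataFrame, path) -> None:
    """Write records to CSV such that :func:`read_birth_records` round-trips."""
    df.to_csv(path, index=False)


def read_clusters(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_clusters(df)


def write_clusters(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def complete_case_split(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (analysable, excluded-missing-blood-loss).

    Complete-case analyses use only records with source-verified blood loss;
    the returned partition always satisfies ``len(cc) + len(excluded) == len(df)``.
    """
    missing = df["blood_loss_ml"].isna()
    return df.loc[~missing], df.loc[missing]
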