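"""Model-ready datasets for the constrained-baseline analysis.

The adjustment set follows the trial's randomization covariates: treatment
exposure (intervention arm AND implementation phase — identically zero in
the baseline phase, which is what "constrained baseline" means), time
period, country, and three cluster-level covariates (annual vaginal births,
baseline severe-event proportion, baseline oxytocin quality), standardized
across clusters for numerical stability.  Clustering enters through random
cluster and cluster-by-period intercepts handled in :mod:`pph_cea.glmm`.

Because every fixed effect is constant within a cluster-period cell, records
are reduced to per-cell sufficient statistics (event counts for the binomial
outcome; mean / within-cell sum of squares for Gaussian outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .records import COUNTRIES, SEVERE_THRESHOLD_ML

CLUSTER_COVARIATES = ["annual_vaginal_births", "baseline_event_proportion", "oxytocin_quality"]


class DesignError(ValueError):
    pass


@dataclass
class Design:
    family: str  # binomial_logit | gaussian_identity
    outcome: str  # severe_pph | total_cost | dalys
    cells: pd.DataFrame  # cluster_id, country, arm, phase, n (+ outcome stats)
    X: np.ndarray
    columns: list[str]
    cluster_code: np.ndarray  # cell -> cluster index
    cluster_ids: list[str]  # index -> cluster_id
    n_records: int

    @property
    def treat(self) -> np.ndarray:
        return self.X[:, self.columns.index("treat")].astype(bool)

    def with_treat_assignment(self, arm_by_cluster: pd.Series) -> "Design":
        """Same cells/covariates with a re-randomized cluster->arm map (permutation)."""
        arm = self.cells["cluster_id"].map(arm_by_cluster)
        treat = ((arm == "intervention") & (self.cells["phase"] == "implementation")).to_numpy(float)
        X = self.X.copy()
        X[:, self.columns.index("treat")] = treat
        return replace(self, X=X)


def standardize_cluster_covariates(clusters: pd.DataFrame) -> pd.DataFrame:
    """Z-score the cluster-level covariates across clusters (sd 0 -> zeros)."""
    out = clusters.copy()
    for c in CLUSTER_COVARIATES:
        x = out[c].astype(float)
        sd = x.std(ddof=0)
        out["z_" + c] = (x - x.mean()) / sd if sd > 0 else 0.0
    return out


def _cell_table(records: pd.DataFrame, clusters: pd.DataFrame, values: pd.Series | None):
    df = records[["cluster_id", "phase"]].copy()
    if values is not None:
        df["y"] = np.asarray(values, float)
    grp = df.groupby(["cluster_id", "phase"], sort=True)
    if values is None:
        cells = grp.size().rename("n").reset_index()
    else:
        cells = grp["y"].agg(n="size", y_mean="mean").reset_index()
        ssw = grp["y"].apply(lambda s: float(((s - s.mean()) ** 2).sum())).rename("y_ssw")
        cells = cells.merge(ssw.reset_index(), on=["cluster_id", "phase"])
    meta = clusters.set_index("cluster_id")
    cells["country"] = cells["cluster_id"].map(meta["country"])
    cells["arm"] = cells["cluster_id"].map(meta["arm"])
    phases = cells.groupby("cluster_id")["phase"].nunique()
    lonely = phases[phases < 2]
    if len(lonely):
        raise DesignError(f"clusters with records in only one phase: {list(lonely.index)[:10]}")
    return cells


def _fixed_effects(cells: pd.DataFrame, clusters_std: pd.DataFrame):
    meta = clusters_std.set_index("cluster_id")
    cols = ["intercept", "treat", "period_implementation"]
    X = [
        np.ones(len(cells)),
        ((cells["arm"] == "intervention") & (cells["phase"] == "implementation")).to_numpy(float),
        (cells["phase"] == "implementation").to_numpy(float),
    ]
    present = [c for c in COUNTRIES if c in set(cells["country"])]
    for c in present[1:]:  # first present country is the reference level
        cols.append(f"country_{c}")
        X.append((cells["country"] == c).to_numpy(float))
    for c in CLUSTER_COVARIATES:
        cols.append("z_" + c)
        X.append(cells["cluster_id"].map(meta["z_" + c]).to_numpy(float))
    return np.column_stack(X), cols


def design_from_cells(cells: pd.DataFrame, clusters: pd.DataFrame, outcome: str) -> Design:
    """Assemble a Design from precomputed cluster-period cell statistics.

    Used by resampling loops (bootstrap) where records never change within a
    cluster, so the per-cell sufficient statistics can be reused directly.
    """
    family = "binomial_logit" if outcome == "severe_pph" else "gaussian_identity"
    clusters_std = standardize_cluster_covariates(clusters)
    X, cols = _fixed_effects(cells, clusters_std)
    cluster_ids = sorted(cells["cluster_id"].unique())
    code = cells["cluster_id"].map({c: i for i, c in enumerate(cluster_ids)}).to_numpy()
    return Design(
        family=family,
        outcome=outcome,
        cells=cells,
        X=X,
        columns=cols,
        cluster_code=code,
        cluster_ids=cluster_ids,
        n_records=int(cells["n"].sum()),
    )


def build_design(
    records: pd.DataFrame,
    clusters: pd.DataFrame,
    outcome: str,
    values: pd.Series | None = None,
) -> Design:
    """Build the model-ready cell dataset for one outcome.

    ``outcome``: ``severe_pph`` (binomial; derived from blood loss),
    ``total_cost`` or ``dalys`` (Gaussian; pass the per-record series as
    ``values``).  Records with missing blood loss must be excluded (or
    imputed) upstream; this function refuses NaN outcomes.
    """
    if outcome == "severe_pph":
        if records["blood_loss_ml"].isna().any():
            raise DesignError("severe-PPH design requires complete blood-loss data")
        ev = (records["blood_loss_ml"] >= SEVERE_THRESHOLD_ML).astype(float)
        cells = _cell_table(records, clusters, None)
        events = (
            records.assign(ev=ev)
            .groupby(["cluster_id", "phase"], sort=True)["ev"]
            .sum()
            .reset_index(drop=True)
        )
        cells["events"] = events.to_numpy()
        family = "binomial_logit"
    elif outcome in ("total_cost", "dalys"):
        if values is None:
            raise DesignError(f"outcome {outcome!r} needs a per-record value series")
        if pd.isna(values).any():
            raise DesignError("Gaussian design requires complete outcome values")
        cells = _cell_table(records, clusters, values)
        family = "gaussian_identity"
    else:
        raise DesignError(f"unknown outcome {outcome!r}")

    clusters_std = standardize_cluster_covariates(clusters)
    X, cols = _fixed_effects(cells, clusters_std)
    cluster_ids = sorted(cells["cluster_id"].unique())
    code = cells["cluster_id"].map({c: i for i, c in enumerate(cluster_ids)}).to_numpy()
    return Design(
        family=family,
        outcome=outcome,
        cells=cells,
        X=X,
        columns=cols,
        cluster_code=code,
        cluster_ids=cluster_ids,
        n_records=len(records),
    )


def fit_design(design: Design, fix_theta=None):
    """Fit the appropriate mixed model for a built design."""
    from . import glmm

    if design.family == "binomial_logit":
        return glmm.fit_binomial(
            design.X,
            design.columns,
            design.cells["events"].to_numpy(float),
            design.cells["n"].to_numpy(float),
            design.cluster_code,
            fix_theta=fix_theta,
        )
    return glmm.fit_gaussian(
        design.X,
        design.columns,
        design.cells["y_mean"].to_numpy(float),
        design.cells["y_ssw"].to_numpy(float),
        design.cells["n"].to_numpy(float),
        design.cluster_code,
        fix_theta=fix_theta,
    )
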