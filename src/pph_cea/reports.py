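"""Structured analysis reports: JSON serialization with exact round-tripping.

Undefined ratios (e.g. an ICER with zero incremental effect) are serialized
as the explicit string marker ``"undefined"``, never as NaN text.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

UNDEFINED = "undefined"


def _encode(obj: Any) -> Any:
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return UNDEFINED
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if hasattr(obj, "item") and callable(obj.item) and not isinstance(obj, (str, bytes)):
        try:
            return _encode(obj.item())
        except Exception:
            return obj
    return obj


def _decode(obj: Any) -> Any:
    if obj == UNDEFINED:
        return float("nan")
    if isinstance(obj, dict):
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


@dataclass
class CeaReport:
    """Full economic-evaluation output for one analysis run."""

    meta: dict = field(default_factory=dict)  # seed, config hash, version, counts
    accounting: dict = field(default_factory=dict)  # N input / analysed / excluded
    group_summaries: dict = field(default_factory=dict)
    adjusted: dict = field(default_factory=dict)  # risk difference, cost, dalys
    icers: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    ceac: list = field(default_factory=list)  # [(lambda, probability), ...]
    dsa: list = field(default_factory=list)  # drape-price rows
    country_level: dict = field(default_factory=dict)
    budget_impact: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)  # e.g. multiple imputation

    def to_dict(self) -> dict:
        return _encode(
            {
                "meta": self.meta,
                "accounting": self.accounting,
                "group_summaries": self.group_summaries,
                "adjusted": self.adjusted,
                "icers": self.icers,
                "thresholds": self.thresholds,
                "ceac": self.ceac,
                "dsa": self.dsa,
                "country_level": self.country_level,
                "budget_impact": self.budget_impact,
                "sensitivity": self.sensitivity,
            }
        )

    @classmethod
    def from_dict(cls, d: dict) -> "CeaReport":
        d = _decode(dict(d))
        return cls(**d)


def write_report(report: CeaReport, path) -> None:
    """Write the machine-readable report; re-reading reproduces numeric fields."""
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, allow_nan=False)


def read_report(path) -> CeaReport:
    with open(path) as fh:
        return CeaReport.from_dict(json.load(fh))


def summarize(report: CeaReport) -> str:
    """Short human-readable summary of the headline numbers."""
    lines = ["Cost-effectiveness analysis summary", "=" * 36]
    adj = report.adjusted
    for key, label, unit in [
        ("risk_difference_pp", "Adjusted severe-PPH risk difference", "pp"),
        ("cost_difference_usd", "Adjusted cost difference", "USD"),
        ("daly_difference", "Adjusted DALY difference", "DALYs"),
    ]:
        if key in adj:
            e = adj[key]
            lines.append(f"{label}: {e['point']:.4g} {unit} (95% CI {e['ci_low']:.4g} to {e['ci_high']:.4g})")
    for key, label in [
        ("per_severe_pph_averted", "ICER per severe PPH averted"),
        ("per_daly_averted", "ICER per DALY averted"),
    ]:
        if key in report.icers:
            r = report.icers[key]
            val = r["icer"] if r["status"] == "icer" else r["status"]
            lines.append(f"{label}: {val if isinstance(val, str) else f'{val:.2f} USD'}")
    thr = report.thresholds
    if thr:
        lines.append(
            f"Weighted thresholds: GDP {thr.get('weighted_gdp', float('nan')):.0f} USD; "
            f"opportunity cost {thr.get('weighted_opportunity_cost', float('nan')):.0f} USD"
        )
    return "\n".join(lines)
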