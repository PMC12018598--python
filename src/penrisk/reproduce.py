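"""One-shot reproduction of the reference study's headline results.

Recomputes every headline quantity from the fixture contingencies (crude
odds ratios with CIs, the four diagnostic proportions with cohort-n Wald
CIs, and the ordinal AUCs for both grading systems) and compares each with
its published counterpart after rounding half-up to the published
precision.

The published values serve only as comparison targets in the report; all
computed values come from the evaluation pipeline at run time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import List, Optional, Tuple

from .cohort import reference_fixture
from .evaluation import (
    CIConvention,
    diagnostic_metrics,
    dichotomize,
    group_odds_ratios,
    ordinal_auc,
    round_half_up,
)
from .grading import RiskGroup

REPORT_SCHEMA_VERSION = "1"

# published headline values: name -> (value, decimal places)
PUBLISHED = {
    "proposed_or_intermediate_vs_low": (25.43, 2),
    "proposed_or_intermediate_vs_low_ci_lower": (5.94, 2),
    "proposed_or_intermediate_vs_low_ci_upper": (108.97, 2),
    "proposed_or_high_vs_low": (177.13, 2),
    "proposed_or_high_vs_low_ci_lower": (40.09, 2),
    "proposed_or_high_vs_low_ci_upper": (782.51, 2),
    "proposed_sensitivity_pct": (98.04, 2),
    "proposed_sensitivity_ci_lower_pct": (96.49, 2),
    "proposed_sensitivity_ci_upper_pct": (99.59, 2),
    "proposed_specificity_pct": (53.43, 2),
    "proposed_specificity_ci_lower_pct": (47.84, 2),
    "proposed_specificity_ci_upper_pct": (59.02, 2),
    "proposed_ppv_pct": (51.28, 2),
    "proposed_ppv_ci_lower_pct": (45.68, 2),
    "proposed_ppv_ci_upper_pct": (56.88, 2),
    "proposed_npv_pct": (98.20, 2),
    "proposed_npv_ci_lower_pct": (96.71, 2),
    "proposed_npv_ci_upper_pct": (99.69, 2),
    "proposed_auc": (0.86, 2),
    "eau_sensitivity_pct": (100.0, 2),
    "eau_specificity_pct": (15.20, 2),
    "eau_specificity_ci_lower_pct": (11.17, 2),
    "eau_specificity_ci_upper_pct": (19.22, 2),
    "eau_ppv_pct": (37.09, 2),
    "eau_ppv_ci_lower_pct": (31.68, 2),
    "eau_ppv_ci_upper_pct": (42.50, 2),
    "eau_npv_pct": (100.0, 2),
    "eau_auc": (0.65, 2),
}


@dataclass(frozen=True)
class ReportRow:
    name: str
    computed: float
    published: float
    rounded: float
    matched: bool
    convention: str
    note: str = ""


def compute_headline_values(ci_convention: CIConvention = CIConvention.COHORT_N) -> dict:
    """All headline quantities, recomputed from the fixture contingencies.

    Percentages are on the 0-100 scale, ORs and AUCs on their natural
    scale; nothing is rounded.
    """
    fx = reference_fixture()
    values = {}

    ors = group_odds_ratios(fx.proposed)
    for group, key in ((RiskGroup.INTERMEDIATE, "intermediate"), (RiskGroup.HIGH, "high")):
        est = ors[group]
        values[f"proposed_or_{key}_vs_low"] = est.point
        values[f"proposed_or_{key}_vs_low_ci_lower"] = est.ci[0]
        values[f"proposed_or_{key}_vs_low_ci_upper"] = est.ci[1]

    for system, contingency in (("proposed", fx.proposed), ("eau", fx.eau)):
        metrics = diagnostic_metrics(dichotomize(contingency), ci_convention, total_n=fx.n_total)
        for metric in ("sensitivity", "specificity", "ppv", "npv"):
            pct, lo, hi = getattr(metrics, metric).as_percent()
            values[f"{system}_{metric}_pct"] = pct
            values[f"{system}_{metric}_ci_lower_pct"] = lo
            values[f"{system}_{metric}_ci_upper_pct"] = hi
        values[f"{system}_auc"] = ordinal_auc(contingency).point
    return values


def reproduction_report(ci_convention: CIConvention = CIConvention.COHORT_N) -> List[ReportRow]:
    """Compare each recomputed headline quantity with its published value;
    ``matched`` means equality after rounding half-up to the published
    precision."""
    computed = compute_headline_values(ci_convention)
    rows = []
    for name, (published, digits) in PUBLISHED.items():
        value = computed[name]
        rounded = round_half_up(value, digits)
        rows.append(
            ReportRow(
                name=name,
                computed=value,
                published=published,
                rounded=rounded,
                matched=rounded == published,
                convention=ci_convention.value if name.endswith("_pct") else "closed_form",
            )
        )
    return rows


def report_as_json(rows: List[ReportRow]) -> str:
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "ci_convention": rows[0].convention if rows else None,
        "quantities": [asdict(r) for r in rows],
        "n_matched": sum(r.matched for r in rows),
        "n_total": len(rows),
    }
    return json.dumps(payload, indent=2)


def report_as_text(rows: List[ReportRow]) -> str:
    width = max(len(r.name) for r in rows)
    lines = [f"{'quantity':<{width}}  computed    published  matched"]
    for r in rows:
        lines.append(f"{r.name:<{width}}  {r.computed:>9.4f}  {r.published:>9.2f}  {'yes' if r.matched else 'NO'}")
    lines.append(f"matched {sum(r.matched for r in rows)}/{len(rows)}")
    return "\n".join(lines)
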