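"""Publication-style reports: cost ledger, effect tables, PSA summaries.

Monetary values are rounded to whole Australian dollars at rendering time
only (half away from zero); negative values carry a plain leading minus.
Every numeric cell in a rendered report equals the in-memory value after
that rounding rule — no hidden recomputation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .costs import CostBreakdown, ParameterSet
from .effects import InterventionContrast
from .psa import PsaResult

__all__ = [
    "round_dollars",
    "ledger_frame",
    "render_cost_ledger",
    "effect_report",
    "psa_report",
]

LEDGER_ROWS = [
    ("A1", "A1: Program staffing costs", 0),
    ("hinh_staff", "HiNH staff (including on-costs)", 1),
    ("in_kind", "Time in kind from other health professionals", 1),
    ("A2", "A2: Program non-staff costs", 0),
    ("travel", "Staff travel", 1),
    ("admin_training", "Administration and training", 1),
    ("stationery", "Stationery and office supplies", 1),
    ("telephone", "Telephone communications", 1),
    ("equipment", "Equipment (annual equivalent)", 1),
    ("office_space", "Office space", 1),
    ("A", "A: Subtotal (program costs)", 0),
    ("B1a", "Avoided ED presentation bed-hours", 1),
    ("B1b", "Shortened ED presentation bed-hours", 1),
    ("B1", "B1: Differences in ED care utilisation", 0),
    ("B2a", "Avoided inpatient admission bed-hours", 1),
    ("B2b", "Shortened inpatient stay bed-hours", 1),
    ("B2", "B2: Differences in inpatient care utilisation", 0),
    ("B3", "B3: Differences in ambulance service utilisation", 0),
    ("B", "B: Subtotal (utilisation differences)", 0),
    ("C", "C: Total net costs (A + B)", 0),
]


def round_dollars(value) -> int:
    """Round to whole dollars, halves away from zero."""
    value = float(value)
    return int(np.sign(value) * np.floor(np.abs(value) + 0.5))


def ledger_frame(breakdown: CostBreakdown, params: ParameterSet | None = None) -> pd.DataFrame:
    """Tabular ledger with item codes, labels and whole-dollar values.

    Individual program-cost line items are included when ``params`` is given;
    otherwise only subtotals and components are listed.
    """
    from .costs import annualize_equipment

    values = breakdown.as_dict()
    if params is not None:
        for item in ("hinh_staff", "in_kind", "travel", "admin_training", "stationery", "telephone", "office_space"):
            values[item] = getattr(params, item)
        values["equipment"] = annualize_equipment(
            params.equipment_price, params.equipment_life, params.discount_rate
        )
    rows = []
    for code, label, indent in LEDGER_ROWS:
        if code not in values:
            continue
        rows.append(
            {
                "code": code,
                "item": ("    " * indent) + label,
                "value": round_dollars(values[code]),
            }
        )
    return pd.DataFrame(rows)


def render_cost_ledger(breakdown: CostBreakdown, params: ParameterSet | None = None) -> str:
    """Aligned text rendering of the annual net-cost ledger."""
    frame = ledger_frame(breakdown, params)
    width = max(len(s) for s in frame["item"])
    lines = ["Summary of induced net costs per annum (AU$)", "=" * (width + 14)]
    for _, row in frame.iterrows():
        lines.append(f"{row['item']:<{width}}  {row['value']:>12,d}")
    return "\n".join(lines)


def effect_report(models: dict, contrasts: dict, means: dict) -> dict:
    """JSON-ready report of fitted ratios, adjusted means and contrasts.

    ``models`` maps outcome name to a fitted estimator; ``contrasts`` to an
    :class:`~hinhcost.effects.InterventionContrast`; ``means`` to an
    adjusted-means frame.
    """
    report = {}
    for name, model in models.items():
        ratios = model.ratios_.loc[["x1", "x2", "x3"]]
        entry = {
            "n_obs": model.n_obs_,
            "deviance_ratio": model.deviance_ratio_,
            "pearson_ratio": model.pearson_ratio_,
            "effects": {
                term: {
                    "ratio": float(row["ratio"]),
                    "ci_low": float(row["ci_low"]),
                    "ci_high": float(row["ci_high"]),
                    "p_value": float(row["p_value"]),
                }
                for term, row in ratios.rename(
                    index={"x1": "hospital", "x2": "year", "x3": "intervention"}
                ).iterrows()
            },
        }
        mean_frame = means.get(name)
        if mean_frame is not None:
            entry["adjusted_means"] = {
                f"{h}-{y}": {
                    "mean": float(r["mean"]),
                    "ci_low": float(r["ci_low"]),
                    "ci_high": float(r["ci_high"]),
                }
                for (h, y), r in mean_frame.iterrows()
            }
        contrast: InterventionContrast | None = contrasts.get(name)
        if contrast is not None:
            entry["intervention_contrast"] = {
                "without": contrast.without.__dict__,
                "with": contrast.with_.__dict__,
                "difference": contrast.difference.__dict__,
                "p_value": contrast.p_value,
            }
        report[name] = entry
    return report


def psa_report(result: PsaResult) -> dict:
    """JSON-ready PSA summary with variance contributions."""
    return {
        "n_trials": result.n_trials,
        "seed": result.seed,
        "summary": result.summary,
        "prob_cost_saving": result.prob_cost_saving(),
        "variance_contributions_pct": {
            k: float(v) for k, v in result.contributions.items()
        },
    }
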