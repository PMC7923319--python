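"""Cohort characteristic tables (baseline + incident-case summaries)."""

from __future__ import annotations

import pandas as pd

from .cohort import CohortResult
from .rates import incidence_rate

__all__ = ["percent", "summarize_cohort"]

_BLOCKS = [
    ("sex", "sex", ["male", "female"]),
    ("age", "age_group", ["30-59", "60-69", "70-79", "80+"]),
    ("education", "education", ["elementary", "short", "medium_long"]),
    ("income", "income_q", [1, 2, 3, 4, 5]),
    ("cohabitation", "cohabitation", ["partner", "single"]),
]


def percent(count: float, total: float) -> float:
    """Within-column percentage rounded to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


def summarize_cohort(result: CohortResult) -> pd.DataFrame:
    """Baseline and incident-case characteristics with stratum incidence rates.

    One row per stratum level in blocks (sex, age, education, income,
    cohabitation): person counts and within-block percentages at inclusion,
    case counts and percentages, and the stratum incidence rate per 100,000
    person-years with its 95% CI.  Case age uses the age group at exit
    (date of diagnosis); other characteristics are taken at inclusion.
    """
    base = result.baseline
    if base.empty:
        raise ValueError("empty cohort")
    cases = base[base["is_case"]]
    n_base, n_cases = len(base), len(cases)
    cells = result.cells
    rows = []
    for block, col, levels in _BLOCKS:
        case_col = "age_group_at_exit" if col == "age_group" else col
        for level in levels:
            nb = int((base[col] == level).sum())
            nc = int((cases[case_col] == level).sum())
            sub = cells[cells[col] == level]
            py = float(sub["person_years"].sum())
            est = incidence_rate(int(sub["cases"].sum()), py) if py > 0 else None
            rows.append(
                {
                    "block": block,
                    "level": str(level),
                    "baseline_n": nb,
                    "baseline_pct": percent(nb, n_base),
                    "cases_n": nc,
                    "cases_pct": percent(nc, n_cases) if n_cases else float("nan"),
                    "ir": round(est.ir, 1) if est else float("nan"),
                    "ci_low": round(est.ci_low, 1) if est else float("nan"),
                    "ci_high": round(est.ci_high, 1) if est else float("nan"),
                }
            )
    return pd.DataFrame(rows)
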