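"""Incidence rates, rate ratios, and the Wald test for a change in inequality.

Rates are reported per 100,000 person-years.  Confidence intervals use the
log-normal approximation for rates based on more than 5 cases and the exact
Poisson (Garwood) interval otherwise.  Ratio inference is carried out on the
log scale, the standard parameterization for relative contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PER",
    "RateEstimate",
    "RateRatio",
    "incidence_rate",
    "rate_ratio",
    "se_from_ci",
    "wald_test_irr_change",
    "yearly_rate_series",
]

PER = 100_000.0  # reporting scale: events per 100,000 person-years
_Z = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class RateEstimate:
    """Incidence rate per 100,000 person-years with a 95% interval."""

    cases: int
    person_years: float
    ir: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RateRatio:
    """Ratio of two incidence rates with 95% interval and log-scale SE."""

    irr: float
    ci_low: float
    ci_high: float
    log_se: float


def incidence_rate(cases: int, person_years: float) -> RateEstimate:
    """Crude incidence rate per 100,000 person-years.

    Exact Poisson interval for cases <= 5 (including the zero-case bound),
    log-normal approximation ``ir * exp(+/- 1.96 / sqrt(cases))`` otherwise.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if cases < 0:
        raise ValueError("cases must be non-negative")
    ir = PER * cases / person_years
    if cases <= 5:
        lo = stats.chi2.ppf(0.025, 2 * cases) / 2 if cases > 0 else 0.0
        hi = stats.chi2.ppf(0.975, 2 * (cases + 1)) / 2
        ci_low = PER * lo / person_years
        ci_high = PER * hi / person_years
    else:
        half = math.exp(_Z / math.sqrt(cases))
        ci_low, ci_high = ir / half, ir * half
    return RateEstimate(cases=int(cases), person_years=float(person_years),
                        ir=ir, ci_low=ci_low, ci_high=ci_high)


def rate_ratio(a: RateEstimate, b: RateEstimate) -> RateRatio:
    """Ratio a/b with log-normal interval; requires cases in both groups."""
    if a.cases == 0 or b.cases == 0:
        raise ValueError("zero cases in a group: use an exact method instead")
    if a.ir <= 0 or b.ir <= 0:
        raise ValueError("rates must be positive")
    irr = a.ir / b.ir
    log_se = math.sqrt(1.0 / a.cases + 1.0 / b.cases)
    return RateRatio(
        irr=irr,
        ci_low=irr * math.exp(-_Z * log_se),
        ci_high=irr * math.exp(_Z * log_se),
        log_se=log_se,
    )


def se_from_ci(ci_low: float, ci_high: float, level_z: float = 1.96) -> float:
    """Recover the log-scale SE of a ratio from its printed 95% CI."""
    if ci_low <= 0 or ci_high <= ci_low:
        raise ValueError("need 0 < ci_low < ci_high")
    return (math.log(ci_high) - math.log(ci_low)) / (2 * level_z)


def wald_test_irr_change(irr1: RateRatio, irr2: RateRatio) -> float:
    """Two-sided Wald p-value for a change in the IRR between two periods.

    z = (log irr2 - log irr1) / sqrt(se1^2 + se2^2), assuming the two
    period-specific ratios are independent.
    """
    if irr1.log_se <= 0 or irr2.log_se <= 0:
        raise ValueError("standard errors must be positive")
    z = (math.log(irr2.irr) - math.log(irr1.irr)) / math.hypot(irr1.log_se, irr2.log_se)
    return float(2 * stats.norm.sf(abs(z)))


def yearly_rate_series(cells: pd.DataFrame, stratify_by: str = "income_q") -> pd.DataFrame:
    """Annual incidence rates, overall and per stratum of one variable.

    ``cells`` is a person-time cell table with ``year``, ``person_years``,
    ``cases`` and the stratification column.  The overall row pools cases and
    person-years (it is not a mean of stratum rates).  Returns one row per
    (year, stratum) with stratum "overall" included.
    """
    if cells.empty:
        raise ValueError("no person-time cells")
    rows = []

    def add(year, stratum, sub):
        cases = int(sub["cases"].sum())
        py = float(sub["person_years"].sum())
        if py <= 0:
            return
        est = incidence_rate(cases, py)
        rows.append(
            {
                "year": int(year),
                "stratum": stratum,
                "cases": cases,
                "person_years": py,
                "ir": est.ir,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )

    for year, by_year in cells.groupby("year"):
        add(year, "overall", by_year)
        for level, sub in by_year.groupby(stratify_by):
            add(year, str(level), sub)
    return pd.DataFrame(rows)
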