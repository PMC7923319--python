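"""Calendar helpers shared by the registry generator and the cohort builder.

Durations are exact calendar-day differences; person-years are days/365.25.
Age-group boundaries fall on calendar birthdays (Feb 29 births roll to Mar 1
in non-leap years), the usual Lexis convention.
"""

from __future__ import annotations

import datetime as dt

DAYS_PER_YEAR = 365.25

#: Age-group labels with half-open [lo, hi) bounds in whole years.
AGE_GROUPS: tuple[tuple[str, int, int | None], ...] = (
    ("30-59", 30, 60),
    ("60-69", 60, 70),
    ("70-79", 70, 80),
    ("80+", 80, None),
)

AGE_GROUP_LABELS = tuple(label for label, _, _ in AGE_GROUPS)
AGE_CUTS = (60, 70, 80)


def anniversary(birth_date: dt.date, years: int) -> dt.date:
    """The ``years``-th birthday; Feb 29 maps to Mar 1 off leap years."""
    try:
        return birth_date.replace(year=birth_date.year + years)
    except ValueError:
        return dt.date(birth_date.year + years, 3, 1)


def age_group_at(birth_date: dt.date, on: dt.date) -> str | None:
    """Age-group label on a given date, or None when younger than 30."""
    if on < anniversary(birth_date, 30):
        return None
    for label, lo, hi in reversed(AGE_GROUPS):
        if on >= anniversary(birth_date, lo):
            return label
    return None


def age_years(birth_date: dt.date, on: dt.date) -> float:
    """Continuous age in 365.25-day years."""
    return (on - birth_date).days / DAYS_PER_YEAR


def year_start(year: int) -> dt.date:
    return dt.date(year, 1, 1)


def to_date(value) -> dt.date | None:
    """Parse ISO strings / dates; pass None and NaN through as None."""
    if value is None:
        return None
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        return dt.date.fromisoformat(value) if value else None
    if value != value:  # NaN
        return None
    raise TypeError(f"cannot interpret {value!r} as a date")
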