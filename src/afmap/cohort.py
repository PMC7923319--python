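"""Open-cohort construction and person-time (Lexis) expansion.

Individuals enter at the later of the study start and their 30th birthday,
and exit at the earliest of first AF diagnosis, death, emigration, or study
end — no re-entry.  Follow-up is split on calendar-year boundaries and on the
60th/70th/80th birthdays; the exit day itself contributes follow-up, so each
follow-up interval is the inclusive day range [entry, exit].  Durations are
exact day counts; person-years are days/365.25.

Socioeconomic covariates follow register conventions: income quintiles are
assigned within calendar year x age band (<65 / >=65) x sex using the income
registered for the *previous* year; missing education is carried forward
(else backward); "unknown" education maps to the lowest level; hypertension
in a year means redeeming at least two distinct antihypertensive drug
classes in that year.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._time import AGE_CUTS, DAYS_PER_YEAR, age_group_at, anniversary
from .synthetic import DRUG_CLASSES, PersonRecord

__all__ = [
    "FollowUp",
    "build_followup",
    "split_person_time",
    "assign_income_quintile",
    "impute_education",
    "derive_hypertension",
    "longest_address",
    "aggregate_cells",
    "build_cohort",
    "CohortResult",
]

CELL_COLUMNS = [
    "year",
    "age_group",
    "sex",
    "income_q",
    "education",
    "cohabitation",
    "region_id",
    "days",
    "person_years",
    "cases",
]


@dataclass(frozen=True)
class FollowUp:
    """One person's at-risk interval within the study window."""

    person_id: str
    entry_date: dt.date
    exit_date: dt.date
    exit_reason: str  # "af" | "death" | "emigration" | "end_of_study"
    is_case: bool

    @property
    def days(self) -> int:
        """Inclusive day count: the exit day contributes follow-up."""
        return (self.exit_date - self.entry_date).days + 1


def build_followup(
    person: PersonRecord, study_window: tuple[dt.date, dt.date]
) -> FollowUp | None:
    """At-risk interval for one person, or None if never eligible.

    Excluded: prevalent cases (AF before entry), persons who die or emigrate
    before entry, and persons who never reach age 30 inside the window.
    Ties between events on the same day resolve as AF > death > emigration,
    so a same-day AF-and-death exit counts as an incident case (AF as cause
    of death).
    """
    start, end = study_window
    if start > end:
        raise ValueError("study window start after end")
    entry = max(start, anniversary(person.birth_date, 30))
    if person.address_periods:
        entry = max(entry, min(p[0] for p in person.address_periods))
    if entry > end:
        return None
    if person.af_date is not None and person.af_date < entry:
        return None  # prevalent case
    events = [
        (person.af_date, "af"),
        (person.death_date, "death"),
        (person.emigration_date, "emigration"),
    ]
    exit_date, reason = end, "end_of_study"
    for date, name in events:  # listed in tie-priority order
        if date is not None and date < exit_date:
            exit_date, reason = date, name
        elif date is not None and date == exit_date and reason == "end_of_study":
            exit_date, reason = date, name
    if exit_date < entry:
        return None
    return FollowUp(
        person_id=person.person_id,
        entry_date=entry,
        exit_date=exit_date,
        exit_reason=reason,
        is_case=(reason == "af"),
    )


def _cut_dates(entry: dt.date, exit_excl: dt.date, birth: dt.date,
               extra: Iterable[dt.date] = ()) -> list[dt.date]:
    cuts = set()
    for year in range(entry.year + 1, exit_excl.year + 1):
        cuts.add(dt.date(year, 1, 1))
    for age in AGE_CUTS:
        b = anniversary(birth, age)
        if entry < b < exit_excl:
            cuts.add(b)
    for d in extra:
        if entry < d < exit_excl:
            cuts.add(d)
    return sorted(cuts)


def split_person_time(fu: FollowUp, birth_date: dt.date) -> list[tuple[int, str, int]]:
    """Split follow-up into (year, age_group, days) pieces.

    Pieces partition the inclusive follow-up interval; cut points fall on
    Jan 1 boundaries and on the 60th/70th/80th birthdays, and the day counts
    sum exactly to the follow-up length.
    """
    exit_excl = fu.exit_date + dt.timedelta(days=1)
    bounds = [fu.entry_date, *_cut_dates(fu.entry_date, exit_excl, birth_date), exit_excl]
    pieces = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        days = (b - a).days
        if days <= 0:
            continue
        group = age_group_at(birth_date, a)
        if group is None:
            raise ValueError("follow-up before age 30 is not allowed")
        pieces.append((a.year, group, days))
    return pieces


def _split_pieces_with_addresses(
    fu: FollowUp, person: PersonRecord
) -> list[tuple[int, str, int, str]]:
    """Year x age-group pieces, further cut at address changes, with region."""
    addr_starts = [p[0] for p in person.address_periods[1:]]
    exit_excl = fu.exit_date + dt.timedelta(days=1)
    bounds = [
        fu.entry_date,
        *_cut_dates(fu.entry_date, exit_excl, person.birth_date, addr_starts),
        exit_excl,
    ]
    pieces = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        days = (b - a).days
        if days <= 0:
            continue
        group = age_group_at(person.birth_date, a)
        region = None
        for start, end, rid, _ in person.address_periods:
            if start <= a <= end:
                region = rid
                break
        if region is None and person.address_periods:
            # follow-up past the last recorded period keeps the last address
            region = person.address_periods[-1][2]
        pieces.append((a.year, group, days, region))
    return pieces


def assign_income_quintile(incomes: Sequence[float]) -> np.ndarray:
    """Quintiles 1..5 (1 = lowest) within one (year, age band, sex) stratum.

    Group sizes differ by at most one before ties; tied incomes all take the
    lowest quintile of their tied block.  Strata with fewer than 5 persons
    cannot support quintiles: everyone gets the middle group, with a warning.
    """
    x = np.asarray(incomes, dtype=float)
    n = len(x)
    if n == 0:
        return np.array([], dtype=int)
    if n < 5:
        warnings.warn(f"income stratum of size {n} < 5: assigning middle quintile")
        return np.full(n, 3, dtype=int)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    q = (5 * ranks) // n + 1
    # tie rule: every member of a tied block shares the block's lowest quintile
    sorted_x = x[order]
    block_q = q[order].copy()
    for i in range(1, n):
        if sorted_x[i] == sorted_x[i - 1]:
            block_q[i] = block_q[i - 1]
    out = np.empty(n, dtype=int)
    out[order] = block_q
    return out


def impute_education(yearly: Mapping[int, str]) -> dict[int, str]:
    """Resolve missing/unknown yearly education codes.

    "unknown" maps to the lowest level (elementary).  "missing" is replaced
    by the previous year's value, or by the following one when no previous
    value exists.  A history with no usable value at all becomes elementary
    throughout, with a warning.
    """
    if not yearly:
        raise ValueError("education history is empty")
    years = sorted(yearly)
    vals = []
    for y in years:
        v = yearly[y]
        if v == "unknown":
            v = "elementary"
        elif v not in ("elementary", "short", "medium_long", "missing"):
            raise ValueError(f"unknown education code {v!r}")
        vals.append(v)
    if all(v == "missing" for v in vals):
        warnings.warn("education missing for all years: assigning elementary")
        return {y: "elementary" for y in years}
    filled: list[str] = []
    for v in vals:  # forward fill
        filled.append(v if v != "missing" else (filled[-1] if filled else "missing"))
    for i in range(len(filled) - 2, -1, -1):  # backward fill the leading gap
        if filled[i] == "missing":
            filled[i] = filled[i + 1]
    return dict(zip(years, filled))


def derive_hypertension(prescriptions: Iterable[tuple[int, str]]) -> dict[int, bool]:
    """Year -> hypertension flag: >= 2 distinct drug classes within the year."""
    classes_by_year: dict[int, set] = {}
    for year, cls in prescriptions:
        if cls not in DRUG_CLASSES:
            raise ValueError(f"unknown antihypertensive class {cls!r}")
        classes_by_year.setdefault(int(year), set()).add(cls)
    return {year: len(cls) >= 2 for year, cls in classes_by_year.items()}


def longest_address(
    periods: Sequence[tuple[dt.date, dt.date, str, tuple[float, float]]],
    window: tuple[dt.date, dt.date],
) -> tuple[str, tuple[float, float]]:
    """The address lived at longest within the window (ties: earliest start)."""
    start, end = window
    best = None
    for p_start, p_end, rid, coords in periods:
        overlap = (min(p_end, end) - max(p_start, start)).days + 1
        if overlap <= 0:
            continue
        key = (-overlap, p_start)
        if best is None or key < best[0]:
            best = (key, rid, coords)
    if best is None:
        raise ValueError("no address period overlaps the window")
    return best[1], best[2]


def aggregate_cells(
    followups: Mapping[str, FollowUp],
    pieces: Mapping[str, Sequence[tuple[int, str, int, str]]],
    covariates: Mapping[tuple[str, int], Mapping[str, object]],
    include_hypertension: bool = False,
) -> pd.DataFrame:
    """Aggregate per-person pieces into stratified person-time cells.

    ``pieces[pid]`` holds (year, age_group, days, region_id) tuples;
    ``covariates[(pid, year)]`` must supply sex, income_q, education and
    cohabitation (plus hypertension when requested) for every contributing
    year.  The incident case of a follow-up is attributed to its final piece.
    Total days and total cases are conserved exactly.
    """
    strata_cols = CELL_COLUMNS[:7] + (["hypertension"] if include_hypertension else [])
    rows = []
    for pid, fu in followups.items():
        person_pieces = list(pieces.get(pid, ()))
        if not person_pieces and fu.days > 0:
            raise ValueError(f"no pieces for person {pid}")
        for j, (year, group, days, region) in enumerate(person_pieces):
            try:
                cov = covariates[(pid, year)]
            except KeyError:
                raise ValueError(f"covariates missing for person {pid}, year {year}")
            row = {
                "year": year,
                "age_group": group,
                "sex": cov["sex"],
                "income_q": int(cov["income_q"]),
                "education": cov["education"],
                "cohabitation": cov["cohabitation"],
                "region_id": region,
                "days": int(days),
                "cases": int(fu.is_case and j == len(person_pieces) - 1),
            }
            if include_hypertension:
                row["hypertension"] = bool(cov.get("hypertension", False))
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=strata_cols + ["days", "person_years", "cases"])
    df = pd.DataFrame(rows)
    cells = df.groupby(strata_cols, as_index=False, sort=True)[["days", "cases"]].sum()
    cells["person_years"] = cells["days"] / DAYS_PER_YEAR
    ordered = strata_cols + ["days", "person_years", "cases"]
    return cells[ordered]


@dataclass
class CohortResult:
    """Built cohort: follow-ups, person-time cells, and entry characteristics."""

    followups: dict[str, FollowUp]
    cells: pd.DataFrame
    baseline: pd.DataFrame  # one row per included person, covariates at entry

    @property
    def total_days(self) -> int:
        return sum(fu.days for fu in self.followups.values())

    @property
    def total_cases(self) -> int:
        return sum(fu.is_case for fu in self.followups.values())


def build_cohort(
    persons: Sequence[PersonRecord],
    study_window: tuple[dt.date, dt.date],
    include_hypertension: bool = False,
    drop_missing_education: bool = False,
) -> CohortResult:
    """Run the full cohort pipeline on a registry.

    Builds follow-ups, splits person-time on calendar years, age-group
    birthdays and address changes, derives yearly covariates (income
    quintiles with the one-year offset, imputed education, cohabitation,
    optionally hypertension), and aggregates to stratified cells.

    ``drop_missing_education`` excludes persons whose education history has
    no registered value at all (the misclassification sensitivity analysis).
    """
    by_id = {p.person_id: p for p in persons}
    followups: dict[str, FollowUp] = {}
    for p in persons:
        if drop_missing_education and all(
            v in ("missing", "unknown") for v in p.yearly_education.values()
        ):
            continue
        fu = build_followup(p, study_window)
        if fu is not None:
            followups[p.person_id] = fu

    pieces = {
        pid: _split_pieces_with_addresses(fu, by_id[pid]) for pid, fu in followups.items()
    }

    # income quintiles within (year, <65/>=65 on Jan 1, sex), one-year offset
    quintile: dict[tuple[str, int], int] = {}
    stratum_members: dict[tuple[int, bool, str], list[tuple[str, float]]] = {}
    for pid, fu in followups.items():
        person = by_id[pid]
        for year in range(fu.entry_date.year, fu.exit_date.year + 1):
            income = person.yearly_income.get(year - 1, np.nan)
            over65 = age_group_at(person.birth_date, dt.date(year, 1, 1)) in ("70-79", "80+") or (
                anniversary(person.birth_date, 65) <= dt.date(year, 1, 1)
            )
            stratum_members.setdefault((year, over65, person.sex), []).append((pid, income))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny strata fall back to the middle group
        for (year, _, _), members in stratum_members.items():
            incomes = np.array([inc for _, inc in members], dtype=float)
            # persons with no registered previous-year income rank lowest
            incomes = np.where(np.isnan(incomes), -np.inf, incomes)
            qs = assign_income_quintile(incomes)
            for (pid, _), q in zip(members, qs):
                quintile[(pid, year)] = int(q)

    covariates: dict[tuple[str, int], dict[str, object]] = {}
    for pid, fu in followups.items():
        person = by_id[pid]
        education = impute_education(person.yearly_education) if person.yearly_education else {}
        hypertension = derive_hypertension(person.prescriptions) if include_hypertension else {}
        edu_years = sorted(education) if education else []
        for year in range(fu.entry_date.year, fu.exit_date.year + 1):
            if year in education:
                edu = education[year]
            elif edu_years:
                # nearest registered year (carried over the window edge)
                nearest = min(edu_years, key=lambda y: abs(y - year))
                edu = education[nearest]
            else:
                edu = "elementary"
            cov = {
                "sex": person.sex,
                "income_q": quintile.get((pid, year), 3),
                "education": edu,
                "cohabitation": person.yearly_cohabitation.get(year, "partner"),
            }
            if include_hypertension:
                cov["hypertension"] = hypertension.get(year, False)
            covariates[(pid, year)] = cov

    cells = aggregate_cells(followups, pieces, covariates, include_hypertension)

    base_rows = []
    for pid, fu in followups.items():
        person = by_id[pid]
        cov = covariates[(pid, fu.entry_date.year)]
        base_rows.append(
            {
                "person_id": pid,
                "entry_date": fu.entry_date,
                "exit_date": fu.exit_date,
                "exit_reason": fu.exit_reason,
                "is_case": fu.is_case,
                "sex": person.sex,
                "age_group": age_group_at(person.birth_date, fu.entry_date),
                "age_group_at_exit": age_group_at(person.birth_date, fu.exit_date),
                "income_q": cov["income_q"],
                "education": cov["education"],
                "cohabitation": cov["cohabitation"],
                "days": fu.days,
            }
        )
    baseline = pd.DataFrame(base_rows)
    return CohortResult(followups=followups, cells=cells, baseline=baseline)
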