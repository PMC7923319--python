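"""Seeded synthetic registry: geography, region effects, and person histories.

The generator is the study's stand-in for restricted national registers.  It
draws municipality-level random effects (an IID component plus an intrinsic
CAR component on the adjacency graph), assigns persons to regions with a
configurable socioeconomic gradient across the map, and simulates first
atrial-fibrillation events from a piecewise-constant hazard over calendar-year
x age-group pieces:

    rate = exp(baseline + covariate effects + u_region + v_region)

per person-year, with independent death and emigration censoring.  Event
times are drawn exactly by inversion of the piecewise-constant cumulative
hazard, i.e. from the very model the downstream estimator assumes.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._time import AGE_CUTS, DAYS_PER_YEAR, age_group_at, anniversary, to_date
from .geography import Geography, generate_lattice_geography

__all__ = [
    "DRUG_CLASSES",
    "PersonRecord",
    "SimulationParams",
    "default_beta",
    "generate_geography",
    "sample_car",
    "simulate_cohort",
    "simulate_region_counts",
    "write_registry",
    "read_registry",
]

#: The six antihypertensive drug classes used for the hypertension proxy.
DRUG_CLASSES = (
    "alpha_blocker",
    "non_loop_diuretic",
    "vasodilator",
    "beta_blocker",
    "calcium_channel_blocker",
    "ras_inhibitor",
)

EDUCATION_LEVELS = ("elementary", "short", "medium_long")


@dataclass
class PersonRecord:
    """One individual's demographic, socioeconomic and event history."""

    person_id: str
    sex: str  # "male" | "female"
    birth_date: dt.date
    yearly_income: dict[int, float] = field(default_factory=dict)
    yearly_education: dict[int, str] = field(default_factory=dict)
    yearly_cohabitation: dict[int, str] = field(default_factory=dict)
    address_periods: list[tuple[dt.date, dt.date, str, tuple[float, float]]] = field(
        default_factory=list
    )
    prescriptions: list[tuple[int, str]] = field(default_factory=list)
    af_date: dt.date | None = None
    death_date: dt.date | None = None
    emigration_date: dt.date | None = None

    def validate(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"bad sex {self.sex!r}")
        prev_end = None
        for start, end, _, _ in self.address_periods:
            if end < start:
                raise ValueError("address period ends before it starts")
            if prev_end is not None and start <= prev_end:
                raise ValueError("address periods overlap or are unordered")
            prev_end = end
        for d in (self.af_date, self.death_date, self.emigration_date):
            if d is not None and d < self.birth_date:
                raise ValueError("event date precedes birth")


@dataclass
class SimulationParams:
    """Parameters of the generative registry model.

    ``beta`` maps covariate levels (e.g. ``"sex[male]"``, ``"age[80+]"``,
    ``"income[1]"``) to log incidence-rate effects; ``baseline_log_rate`` is
    the log hazard per person-year of the reference stratum (female, 30-59,
    highest income quintile, medium/long education, living with a partner).
    ``tau_u``/``tau_v`` are the precisions of the IID and intrinsic-CAR
    municipality components.
    """

    n_persons: int = 20_000
    study_window: tuple[dt.date, dt.date] = (dt.date(2006, 1, 1), dt.date(2015, 12, 31))
    beta: Mapping[str, float] = field(default_factory=lambda: default_beta())
    baseline_log_rate: float = math.log(70e-5)
    tau_u: float = 100.0
    tau_v: float = 50.0
    seed: int = 0
    # generator texture ---------------------------------------------------
    ses_gradient: float = 0.6  # SES mean shift (SD units) west->east across the map
    move_prob: float = 0.08  # probability of one address change in the window
    emigration_rate: float = 0.003  # per person-year
    death_rates: Mapping[str, float] = field(
        default_factory=lambda: {"30-59": 0.002, "60-69": 0.010, "70-79": 0.030, "80+": 0.110}
    )
    missing_education_prob: float = 0.02
    unknown_education_prob: float = 0.03
    with_prescriptions: bool = True
    age_range_at_start: tuple[float, float] = (25.0, 92.0)

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise ValueError("precisions must be positive")
        if self.study_window[0] >= self.study_window[1]:
            raise ValueError("study_window start must precede end")


def default_beta() -> dict[str, float]:
    """Covariate log-effects of realistic register-epidemiology magnitude.

    Age effects follow the steep observed gradient of AF incidence; the
    socioeconomic effects are moderate (lowest-vs-highest income IRR ~1.4).
    """
    return {
        "sex[male]": math.log(1.25),
        "age[60-69]": math.log(5.8),
        "age[70-79]": math.log(13.0),
        "age[80+]": math.log(28.0),
        "income[1]": math.log(1.40),
        "income[2]": math.log(1.28),
        "income[3]": math.log(1.16),
        "income[4]": math.log(1.08),
        "education[elementary]": math.log(1.20),
        "education[short]": math.log(1.08),
        "cohabitation[single]": math.log(1.18),
    }


def generate_geography(n_rows: int, n_cols: int, cell_km: float, seed: int = 0) -> Geography:
    """Rook lattice geography (see :func:`afmap.geography.generate_lattice_geography`)."""
    return generate_lattice_geography(n_rows, n_cols, cell_km, seed)


# --------------------------------------------------------------------------
# Region random effects
# --------------------------------------------------------------------------


def sample_car(geography: Geography, tau_v: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one realization of the intrinsic CAR field on the geography graph.

    The intrinsic CAR precision matrix is tau_v * Q with Q the graph
    Laplacian, which is singular (constant null space).  Sampling uses the
    eigendecomposition of Q restricted to the non-null eigenspace, which is
    exactly a draw from the pseudo-inverse covariance on the sum-to-zero
    subspace; the draw is recentred to remove numerical drift.
    """
    geography.require_connected()
    n = geography.n_regions
    idx = geography.index()
    q = np.zeros((n, n))
    for edge in geography.all_edges():
        a, b = (idx[e] for e in edge)
        q[a, a] += 1
        q[b, b] += 1
        q[a, b] -= 1
        q[b, a] -= 1
    eigval, eigvec = np.linalg.eigh(q)
    # connected graph -> exactly one (near-)zero eigenvalue
    keep = eigval > 1e-10 * eigval.max()
    z = rng.standard_normal(keep.sum())
    v = eigvec[:, keep] @ (z / np.sqrt(tau_v * eigval[keep]))
    return v - v.mean()


def _draw_region_effects(
    params: SimulationParams, geography: Geography, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    u = rng.normal(0.0, 1.0 / math.sqrt(params.tau_u), geography.n_regions)
    v = sample_car(geography, params.tau_v, rng)
    return u, v


# --------------------------------------------------------------------------
# Person-level simulation
# --------------------------------------------------------------------------


def _beta_lookup(beta: Mapping[str, float], key: str) -> float:
    return float(beta.get(key, 0.0))


def _person_linear_predictor(
    beta: Mapping[str, float],
    sex: str,
    age_group: str,
    income_q: int,
    education: str,
    cohabitation: str,
) -> float:
    lp = 0.0
    if sex == "male":
        lp += _beta_lookup(beta, "sex[male]")
    if age_group != "30-59":
        lp += _beta_lookup(beta, f"age[{age_group}]")
    if income_q != 5:
        lp += _beta_lookup(beta, f"income[{income_q}]")
    if education != "medium_long":
        lp += _beta_lookup(beta, f"education[{education}]")
    if cohabitation == "single":
        lp += _beta_lookup(beta, f"cohabitation[{cohabitation}]")
    return lp


def _piece_boundaries(entry: dt.date, end: dt.date, birth: dt.date, extra: Sequence[dt.date]):
    """Sorted cut dates strictly inside (entry, end]: Jan 1s, decade birthdays, moves."""
    cuts = set()
    for year in range(entry.year + 1, end.year + 1):
        cuts.add(dt.date(year, 1, 1))
    for age in AGE_CUTS:
        b = anniversary(birth, age)
        if entry < b <= end:
            cuts.add(b)
    for d in extra:
        if entry < d <= end:
            cuts.add(d)
    return sorted(cuts)


def _invert_piecewise(durations_years, rates, exp_draw):
    """First-passage time (years) of a piecewise-constant cumulative hazard.

    Returns the time from the start of the first piece at which the
    cumulative hazard reaches ``exp_draw``, or None if it never does.
    """
    acc = 0.0
    elapsed = 0.0
    for dur, rate in zip(durations_years, rates):
        step = rate * dur
        if acc + step >= exp_draw:
            if rate <= 0:
                return None
            return elapsed + (exp_draw - acc) / rate
        acc += step
        elapsed += dur
    return None


def simulate_cohort(params: SimulationParams, geography: Geography) -> list[PersonRecord]:
    """Simulate an open synthetic registry over the study window.

    Persons are generated with ages spanning entry before and during the
    window; follow-up hazard applies from the later of the window start and
    the 30th birthday.  AF, death and emigration are competing events drawn
    by independent cumulative-hazard inversion over the person's calendar
    x age-group x address pieces.  Fully reproducible for a fixed seed.
    """
    params.validate()
    geography.require_connected()
    rng = np.random.default_rng(params.seed)

    n = params.n_persons
    win_start, win_end = params.study_window
    u, v = _draw_region_effects(params, geography, rng)
    region_ids = geography.region_ids
    idx = geography.index()
    coords = geography.coord_array()
    xs = coords[:, 0]
    ses_region = params.ses_gradient * (xs - xs.mean()) / (xs.std() + 1e-12)

    # person-level attributes (vectorized draws)
    region_i = rng.integers(0, len(region_ids), n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    age_lo, age_hi = params.age_range_at_start
    # age pyramid close to an adult register population: most mass 25-60,
    # thinning toward old age
    bands = np.array([(25.0, 60.0), (60.0, 70.0), (70.0, 80.0), (80.0, 92.0)])
    weights = np.array([0.68, 0.17, 0.09, 0.06])
    band_i = rng.choice(4, n, p=weights)
    ages0 = rng.uniform(bands[band_i, 0], bands[band_i, 1])
    ages0 = np.clip(ages0, age_lo, age_hi)
    birth_ordinals = win_start.toordinal() - np.round(ages0 * DAYS_PER_YEAR).astype(int)
    ses = rng.normal(ses_region[region_i], 1.0)
    # population quintile of the latent SES score (1 = lowest income)
    qedges = np.quantile(ses, [0.2, 0.4, 0.6, 0.8])
    income_q = 1 + np.searchsorted(qedges, ses)
    edu_p = rng.random(n)
    ses_rank = (ses - ses.mean()) / (ses.std() + 1e-12)
    p_elem = np.clip(0.35 - 0.15 * ses_rank, 0.05, 0.85)
    p_short = 0.45
    education = np.where(
        edu_p < p_elem, "elementary", np.where(edu_p < p_elem + p_short, "short", "medium_long")
    )
    cohab_single = rng.random(n) < np.clip(0.25 + 0.006 * (ages0 - 50), 0.1, 0.8)

    years = range(win_start.year - 1, win_end.year + 1)
    persons: list[PersonRecord] = []
    for k in range(n):
        birth = dt.date.fromordinal(int(birth_ordinals[k]))
        rid = region_ids[int(region_i[k])]
        pid = f"P{k + 1:07d}"
        px, py = geography.coords[rid]
        cell_jit = rng.uniform(-0.45, 0.45, 2)
        # km coordinates rounded to 1e-6 (mm) so CSV round-trips are exact
        home = (round(float(px + cell_jit[0] * 5.0), 6), round(float(py + cell_jit[1] * 5.0), 6))

        # address history: mostly a single lifelong address, some one-time movers
        addr_events: list[dt.date] = []
        periods: list[tuple[dt.date, dt.date, str, tuple[float, float]]] = []
        if rng.random() < params.move_prob:
            move_day = win_start + dt.timedelta(days=int(rng.integers(30, (win_end - win_start).days - 30)))
            new_region = region_ids[int(rng.integers(0, len(region_ids)))]
            nx_, ny_ = geography.coords[new_region]
            jit2 = rng.uniform(-0.45, 0.45, 2)
            periods.append((birth, move_day - dt.timedelta(days=1), rid, home))
            periods.append(
                (move_day, win_end, new_region,
                 (round(float(nx_ + jit2[0] * 5.0), 6), round(float(ny_ + jit2[1] * 5.0), 6)))
            )
            addr_events.append(move_day)
        else:
            periods.append((birth, win_end, rid, home))

        # yearly socioeconomic history (income rank-monotone in latent SES)
        yearly_income: dict[int, float] = {}
        yearly_edu: dict[int, str] = {}
        yearly_cohab: dict[int, str] = {}
        base_edu = str(education[k])
        for year in years:
            yearly_income[year] = float(
                math.exp(10.0 + 0.6 * ses[k] + 0.05 * rng.standard_normal())
            )
            r = rng.random()
            if r < params.missing_education_prob:
                yearly_edu[year] = "missing"
            elif r < params.missing_education_prob + params.unknown_education_prob:
                yearly_edu[year] = "unknown"
            else:
                yearly_edu[year] = base_edu
            yearly_cohab[year] = "single" if cohab_single[k] else "partner"

        rec = PersonRecord(
            person_id=pid,
            sex=str(sex[k]),
            birth_date=birth,
            yearly_income=yearly_income,
            yearly_education=yearly_edu,
            yearly_cohabitation=yearly_cohab,
            address_periods=periods,
        )

        # competing event times by piecewise cumulative-hazard inversion
        entry = max(win_start, anniversary(birth, 30))
        if entry <= win_end:
            cuts = _piece_boundaries(entry, win_end, birth, addr_events)
            bounds = [entry, *cuts, win_end + dt.timedelta(days=1)]
            durations, af_rates, death_rates = [], [], []
            for a, b in zip(bounds[:-1], bounds[1:]):
                dur = (b - a).days / DAYS_PER_YEAR
                if dur <= 0:
                    continue
                grp = age_group_at(birth, a) or "30-59"
                reg = next(
                    (p[2] for p in periods if p[0] <= a <= p[1]), periods[-1][2]
                )
                ri = idx[reg]
                lp = params.baseline_log_rate + _person_linear_predictor(
                    params.beta, str(sex[k]), grp, int(income_q[k]), base_edu,
                    "single" if cohab_single[k] else "partner",
                ) + u[ri] + v[ri]
                durations.append(dur)
                af_rates.append(math.exp(lp))
                death_rates.append(params.death_rates.get(grp, 0.01))

            draws = rng.exponential(1.0, 3)
            t_af = _invert_piecewise(durations, af_rates, draws[0])
            t_death = _invert_piecewise(durations, death_rates, draws[1])
            t_emig = _invert_piecewise(
                durations, [params.emigration_rate] * len(durations), draws[2]
            )

            def _to_date(t):
                return entry + dt.timedelta(days=int(t * DAYS_PER_YEAR)) if t is not None else None

            d_af, d_death, d_emig = _to_date(t_af), _to_date(t_death), _to_date(t_emig)
            # earliest event wins; later events are never observed
            candidates = [(d, name) for d, name in
                          ((d_af, "af"), (d_death, "death"), (d_emig, "emig")) if d is not None]
            if candidates:
                candidates.sort(key=lambda c: c[0])
                first_date = candidates[0][0]
                for d, name in candidates:
                    if d != first_date:
                        break
                    if name == "af":
                        rec.af_date = d
                    elif name == "death":
                        rec.death_date = d
                    else:
                        rec.emigration_date = d

        # prescriptions (hypertension proxy); prevalence rises with age and low SES
        if params.with_prescriptions:
            p_ht = min(0.6, max(0.02, 0.02 + 0.006 * (ages0[k] - 40) - 0.03 * ses_rank[k]))
            if rng.random() < p_ht:
                n_classes = 2 + int(rng.random() < 0.3)
                classes = rng.choice(len(DRUG_CLASSES), n_classes, replace=False)
                for year in range(win_start.year, win_end.year + 1):
                    if rng.random() < 0.8:
                        for c in classes:
                            rec.prescriptions.append((year, DRUG_CLASSES[int(c)]))
            elif rng.random() < 0.05:
                rec.prescriptions.append(
                    (int(rng.integers(win_start.year, win_end.year + 1)),
                     DRUG_CLASSES[int(rng.integers(0, len(DRUG_CLASSES)))])
                )

        persons.append(rec)
    return persons


# --------------------------------------------------------------------------
# Direct region-level count simulation (fast parameter-recovery route)
# --------------------------------------------------------------------------


class SimulatedCounts(NamedTuple):
    cells: pd.DataFrame
    u: np.ndarray
    v: np.ndarray


def simulate_region_counts(
    params: SimulationParams,
    geography: Geography,
    exposures: pd.DataFrame,
    region_effects: tuple[np.ndarray, np.ndarray] | None = None,
) -> SimulatedCounts:
    """Draw Poisson counts per region-stratum, bypassing person simulation.

    ``exposures`` must have a ``region_id`` column, a ``person_years`` column
    (>= 0), and optionally categorical covariate columns (``sex``, ``age``,
    ``income``, ``education``, ``cohabitation``) whose levels select entries
    of ``params.beta`` via the ``name[level]`` convention.  Returns the cells
    with a ``cases`` column plus the region effects used.
    """
    params.validate()
    geography.require_connected()
    if (exposures["person_years"] < 0).any():
        raise ValueError("exposures must be non-negative")
    unknown = set(exposures["region_id"]) - set(geography.region_ids)
    if unknown:
        raise ValueError(f"unknown regions in exposures: {sorted(unknown)}")

    rng = np.random.default_rng(params.seed)
    if region_effects is None:
        u, v = _draw_region_effects(params, geography, rng)
    else:
        u, v = (np.asarray(a, dtype=float) for a in region_effects)

    idx = geography.index()
    ri = exposures["region_id"].map(idx).to_numpy()
    lp = np.full(len(exposures), params.baseline_log_rate)
    for col in ("sex", "age", "income", "education", "cohabitation", "hypertension"):
        if col in exposures.columns:
            keys = col + "[" + exposures[col].astype(str) + "]"
            lp += keys.map(lambda k: _beta_lookup(params.beta, k)).to_numpy()
    mean = exposures["person_years"].to_numpy() * np.exp(lp + u[ri] + v[ri])
    cells = exposures.copy()
    cells["cases"] = rng.poisson(mean)
    return SimulatedCounts(cells=cells, u=u, v=v)


# --------------------------------------------------------------------------
# Registry CSV round-trip
# --------------------------------------------------------------------------

_PERSON_COLS = ["person_id", "sex", "birth_date", "af_date", "death_date", "emigration_date"]


def write_registry(persons: Sequence[PersonRecord], outdir: str | Path) -> dict[str, Path]:
    """Write the registry as four plain CSV tables; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iso = lambda d: d.isoformat() if d is not None else ""
    persons_rows, year_rows, addr_rows, rx_rows = [], [], [], []
    for p in persons:
        persons_rows.append(
            [p.person_id, p.sex, iso(p.birth_date), iso(p.af_date), iso(p.death_date),
             iso(p.emigration_date)]
        )
        for year in sorted(p.yearly_income):
            year_rows.append(
                [p.person_id, year, p.yearly_income[year],
                 p.yearly_education.get(year, "missing"),
                 p.yearly_cohabitation.get(year, "partner")]
            )
        for start, end, rid, (x, y) in p.address_periods:
            addr_rows.append([p.person_id, iso(start), iso(end), rid, x, y])
        for year, cls in p.prescriptions:
            rx_rows.append([p.person_id, year, cls])
    paths = {}
    frames = {
        "persons": pd.DataFrame(persons_rows, columns=_PERSON_COLS),
        "person_years": pd.DataFrame(
            year_rows, columns=["person_id", "year", "income", "education", "cohabitation"]
        ),
        "addresses": pd.DataFrame(
            addr_rows, columns=["person_id", "start", "end", "region_id", "x_km", "y_km"]
        ),
        "prescriptions": pd.DataFrame(rx_rows, columns=["person_id", "year", "drug_class"]),
    }
    for name, df in frames.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_registry(outdir: str | Path) -> list[PersonRecord]:
    """Load a registry written by :func:`write_registry`."""
    outdir = Path(outdir)
    persons_df = pd.read_csv(outdir / "persons.csv", dtype={"person_id": str}, keep_default_na=False)
    years_df = pd.read_csv(outdir / "person_years.csv", dtype={"person_id": str})
    addr_df = pd.read_csv(outdir / "addresses.csv", dtype={"person_id": str})
    rx_path = outdir / "prescriptions.csv"
    rx_df = pd.read_csv(rx_path, dtype={"person_id": str}) if rx_path.exists() else None

    records: dict[str, PersonRecord] = {}
    for row in persons_df.itertuples(index=False):
        records[row.person_id] = PersonRecord(
            person_id=row.person_id,
            sex=row.sex,
            birth_date=to_date(row.birth_date),
            af_date=to_date(row.af_date or None),
            death_date=to_date(row.death_date or None),
            emigration_date=to_date(row.emigration_date or None),
        )
    for row in years_df.itertuples(index=False):
        rec = records[row.person_id]
        rec.yearly_income[int(row.year)] = float(row.income)
        rec.yearly_education[int(row.year)] = str(row.education)
        rec.yearly_cohabitation[int(row.year)] = str(row.cohabitation)
    for row in addr_df.itertuples(index=False):
        records[row.person_id].address_periods.append(
            (to_date(row.start), to_date(row.end), row.region_id, (float(row.x_km), float(row.y_km)))
        )
    if rx_df is not None:
        for row in rx_df.itertuples(index=False):
            records[row.person_id].prescriptions.append((int(row.year), str(row.drug_class)))
    out = list(records.values())
    for rec in out:
        rec.address_periods.sort(key=lambda p: p[0])
    return out
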