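import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from afmap.geography import generate_lattice_geography
from afmap.synthetic import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def lattice98():
    """The 98-region 7x14 rook lattice used throughout."""
    return generate_lattice_geography(7, 14, 10.0, seed=1)


@pytest.fixture(scope="session")
def small_lattice():
    return generate_lattice_geography(3, 4, 10.0, seed=1)


@pytest.fixture(scope="session")
def small_registry(small_lattice):
    """A small but fully featured synthetic registry (shared, read-only)."""
    params = SimulationParams(
        n_persons=3000,
        study_window=(dt.date(2006, 1, 1), dt.date(2015, 12, 31)),
        seed=42,
    )
    return params, simulate_cohort(params, small_lattice)


@pytest.fixture(scope="session")
def sex_exposures(lattice98):
    """98 regions x 2 sexes exposure table for region-count simulation."""
    rows = [
        {"region_id": rid, "sex": sex, "person_years": 2000.0}
        for rid in lattice98.region_ids
        for sex in ("female", "male")
    ]
    return pd.DataFrame(rows)
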