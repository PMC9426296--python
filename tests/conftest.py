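import datetime as dt

import pytest

from doserecon.core import ACCIDENT_DATE
from doserecon.distributions import point
from doserecon.mission import AkrGrid, ItineraryEntry
from doserecon.synthetic import CohortConfig, generate_cohort

ACCIDENT = ACCIDENT_DATE
FAR_FUTURE = dt.date(2010, 1, 1)


@pytest.fixture(scope="session")
def small_bundle():
    """Ten-trio synthetic cohort (two per category), fixed seed."""
    config = CohortConfig(
        n_trios={"A": 2, "B": 2, "C": 2, "D": 2, "E": 2}, n_settlements=10
    )
    return generate_cohort(config, seed=42)


@pytest.fixture()
def unit_entry():
    """Single itinerary entry with all-point parameters (AKR=dt=LF=1)."""
    return ItineraryEntry(
        day=dt.date(1986, 6, 1),
        location_id="L0",
        activity="work",
        duration=point(1.0),
        lf=point(1.0),
    )


@pytest.fixture()
def unit_grid():
    grid = AkrGrid()
    grid.add("L0", ACCIDENT, point(1.0))
    return grid
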