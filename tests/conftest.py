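import datetime as dt

import pytest

from aggresidence.simulate import SimConfig, build_scenario
from aggresidence.types import Shark, Station, StudyWindow, TagDeployment


def ts(*args):
    return dt.datetime(*args)


@pytest.fixture(scope="session")
def small_scenario():
    """Shared small simulated scenario (12 sharks, 2 years)."""
    cfg = SimConfig(seed=7, n_sharks=12, years=2)
    return build_scenario(cfg)


@pytest.fixture
def window():
    return StudyWindow(dt.date(2012, 1, 1), dt.date(2012, 12, 31))


@pytest.fixture
def basic_station():
    def make(station_id="ST01", region="exposed", lat=20.0, lon=40.0,
             intervals=None, nominal_range_m=540.0):
        return Station(
            station_id, region, lat, lon,
            intervals if intervals is not None
            else [(ts(2012, 1, 1), ts(2013, 1, 1))],
            nominal_range_m,
        )

    return make


@pytest.fixture
def tagged_shark():
    def make(shark_id="WS001", sex="F", length=4.0, start=ts(2012, 3, 1, 10)):
        dep = TagDeployment(f"T-{shark_id}", shark_id, start)
        return Shark(shark_id, sex, length, [dep])

    return make
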