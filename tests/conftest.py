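import logging

import pytest
from hypothesis import settings

import geoexposure as gx

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from geoexposure.timeuse import build_places

# silence the >168 h/week warnings the generator legitimately triggers
logging.getLogger("geoexposure.timeuse").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def city():
    return gx.generate_city(gx.CityConfig(seed=7))


@pytest.fixture(scope="session")
def cohort500(city):
    return gx.generate_cohort(city, gx.CohortConfig(seed=11, n_participants=500))


@pytest.fixture(scope="session")
def places500(city, cohort500):
    by = {}
    for r in cohort500.reports:
        by.setdefault(r.participant_id, []).append(r)
    return {pid: build_places(rs, city) for pid, rs in by.items()}


@pytest.fixture(scope="session")
def exposures500(city, places500):
    table, excluded, no_time = gx.compute_exposures(places500, city)
    return table, excluded, no_time


def make_report(pid="P1", ltype="live_sleep", lat=39.30, lon=-76.61, days=7, hours=16):
    return gx.LocationReport(
        participant_id=pid,
        location_type=ltype,
        lat=lat,
        lon=lon,
        days_per_week=days,
        hours_per_day=hours,
    )
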