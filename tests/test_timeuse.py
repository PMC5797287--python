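"""Time-use resolution, fractions, and exposure measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import geoexposure as gx
from geoexposure.geospatial import UniquePlace
from geoexposure.timeuse import (
    per_type_exposure,
    percent_time_by_type,
    time_fractions,
    weighted_exposure,
)

from conftest import make_report


def place(pid="P1", k=0, types=("live_sleep",), t=None, area="A000", rep=(39.2, -76.7)):
    return UniquePlace(
        participant_id=pid,
        place_id=f"{pid}:{k}",
        member_types=tuple(types),
        representative=rep,
        member_hours={ty: t for ty in types},
        weekly_hours=t,
        area_id=area,
    )


# ---------------------------------------------------------------------------
# weekly_hours


@pytest.mark.parametrize(
    "days,hours,expected",
    [
        (7, 16, 112.0),
        (gx.LESS_THAN_ONE, 2, 1.0),
        (3, gx.LESS_THAN_ONE, 1.5),
        (None, 5, None),
        (7, None, None),
        (0, 10, 0.0),
    ],
)
def test_weekly_hours_resolution(days, hours, expected):
    assert gx.weekly_hours(days, hours) == expected


def test_weekly_hours_zero_policy_and_range_errors():
    policy = gx.TimeUsePolicy(missing_policy="zero")
    assert gx.weekly_hours(None, 5, policy) == 0.0
    with pytest.raises(ValueError):
        gx.weekly_hours(8, 5)
    with pytest.raises(ValueError):
        gx.weekly_hours(5, 26)


def test_configurable_token_values():
    policy = gx.TimeUsePolicy(less_than_one_day=0.25, less_than_one_hour=0.75)
    assert gx.weekly_hours(gx.LESS_THAN_ONE, 4, policy) == 1.0
    assert gx.weekly_hours(2, gx.LESS_THAN_ONE, policy) == 1.5


# ---------------------------------------------------------------------------
# time_fractions


def test_time_fractions_basic():
    assert time_fractions([place(t=112.0)]) == {"P1:0": 1.0}
    fr = time_fractions([place(k=0, t=30.0), place(k=1, t=10.0, types=("work_earn",))])
    assert fr == {"P1:0": 0.75, "P1:1": 0.25}


def test_time_fractions_missing_and_zero():
    # missing t excluded entirely; zero t retained with w = 0
    fr = time_fractions(
        [place(k=0, t=90.0), place(k=1, t=None), place(k=2, t=0.0)]
    )
    assert fr == {"P1:0": 1.0, "P1:2": 0.0}
    # no usable time data -> NO_TIME_DATA (empty mapping)
    assert time_fractions([place(t=None), place(k=1, t=0.0)]) == {}


@given(st.lists(st.floats(0.1, 168.0), min_size=1, max_size=6))
@settings(max_examples=200, deadline=None)
def test_fractions_sum_to_one(ts):
    places = [place(k=i, t=t) for i, t in enumerate(ts)]
    assert sum(time_fractions(places).values()) == pytest.approx(1.0, abs=1e-12)


@given(
    st.lists(st.floats(0.5, 100.0), min_size=2, max_size=6),
    st.floats(0.01, 50.0),
)
@settings(max_examples=100, deadline=None)
def test_scale_equivariance(ts, scale):
    base = [place(k=i, t=t) for i, t in enumerate(ts)]
    scaled = [place(k=i, t=t * scale) for i, t in enumerate(ts)]
    f1, f2 = time_fractions(base), time_fractions(scaled)
    for k in f1:
        assert f1[k] == pytest.approx(f2[k], rel=1e-9)


# ---------------------------------------------------------------------------
# weighted / per-type exposure


def test_weighted_exposure_examples(city):
    x0 = city.value("A000", "violent_crime_rate")
    x1 = city.value("A001", "violent_crime_rate")
    assign = {"P1:0": "A000", "P1:1": "A001"}
    assert weighted_exposure({"P1:0": 1.0}, assign, city, "violent_crime_rate") == x0
    e = weighted_exposure({"P1:0": 0.5, "P1:1": 0.5}, assign, city, "violent_crime_rate")
    assert e == pytest.approx((x0 + x1) / 2.0)
    e = weighted_exposure({"P1:0": 0.75, "P1:1": 0.25}, assign, city, "violent_crime_rate")
    assert e == pytest.approx(0.75 * x0 + 0.25 * x1)


def test_weighted_exposure_unknown_indicator(city):
    with pytest.raises(KeyError):
        weighted_exposure({"P1:0": 1.0}, {"P1:0": "A000"}, city, "nope")


def test_per_type_exposure_all_types_one_place(city):
    p = place(types=gx.LOCATION_TYPES, t=112.0, area="A007")
    expo = per_type_exposure([p], city, "violent_crime_rate")
    x = city.value("A007", "violent_crime_rate")
    assert expo == {t: x for t in gx.LOCATION_TYPES}


def test_per_type_exposure_skips_unreported_types(city):
    p = place(types=("live_sleep", "socialize"), t=100.0)
    expo = per_type_exposure([p], city, "violent_crime_rate")
    assert "inject" not in expo and set(expo) == {"live_sleep", "socialize"}


def test_percent_time_overlap_and_split():
    p = place(types=("live_sleep", "socialize"), t=100.0)
    shares = percent_time_by_type([p])
    assert shares == {"live_sleep": 1.0, "socialize": 1.0}

    ps = [
        place(k=0, types=("live_sleep",), t=90.0),
        place(k=1, types=("work_earn",), t=10.0),
    ]
    shares = percent_time_by_type(ps)
    assert shares == {"live_sleep": 0.9, "work_earn": 0.1}


# ---------------------------------------------------------------------------
# cohort-level properties


def test_convexity_of_weighted_exposure(city, places500, exposures500):
    """Weighted E lies within [min, max] of the visited areas' values."""
    table, excluded, _ = exposures500
    weighted = table[table.measure == "weighted"]
    assert not weighted.empty
    for name in city.indicator_names:
        sub = weighted[weighted.indicator == name].set_index("participant_id")["value"]
        for pid, e in sub.items():
            xs = [
                city.value(p.area_id, name)
                for p in places500[pid]
                if p.weekly_hours is not None
            ]
            assert min(xs) - 1e-9 <= e <= max(xs) + 1e-9


def test_single_area_participants_have_equal_measures(city):
    """All places in one area -> weighted E equals every per-type E."""
    reports = [
        make_report(ltype="live_sleep", lat=39.205, lon=-76.695, days=7, hours=16),
        make_report(ltype="socialize", lat=39.2051, lon=-76.6951, days=2, hours=4),
    ]
    places = gx.build_places(reports, city)
    assert len({p.area_id for p in places}) == 1
    table, _, _ = gx.compute_exposures({"P1": places}, city)
    for name in city.indicator_names:
        vals = table[table.indicator == name]["value"]
        assert vals.nunique() == 1


def test_duplicate_hours_rule_max_vs_mean():
    reports = [
        make_report(ltype="live_sleep", days=7, hours=16),
        make_report(ltype="socialize", days=2, hours=4),
    ]
    p_max = gx.build_places(reports, policy=gx.TimeUsePolicy(duplicate_hours_rule="max"))
    p_mean = gx.build_places(reports, policy=gx.TimeUsePolicy(duplicate_hours_rule="mean"))
    assert p_max[0].weekly_hours == 112.0
    assert p_mean[0].weekly_hours == (112.0 + 8.0) / 2.0


def test_unassigned_policies(city):
    inside = make_report(ltype="live_sleep", lat=39.205, lon=-76.695, days=7, hours=16)
    outside = make_report(ltype="work_earn", lat=38.0, lon=-78.0, days=2, hours=4)
    places = gx.build_places([inside, outside], city)
    assert any(p.area_id == gx.UNASSIGNED for p in places)

    table, excluded, _ = gx.compute_exposures({"P1": places}, city)
    assert excluded == ["P1"] and table.empty

    table, excluded, _ = gx.compute_exposures(
        {"P1": places}, city, policy=gx.TimeUsePolicy(unassigned_policy="renormalize")
    )
    assert excluded == []
    weighted = table[table.measure == "weighted"]
    # renormalized over the single assigned place -> E equals that area's X
    for _, row in weighted.iterrows():
        assert row.value == city.value(places[0].area_id, row.indicator)
    assert "work_earn" not in set(table.measure)


def test_no_time_data_flagged(city):
    r = make_report(ltype="live_sleep", lat=39.205, lon=-76.695, days=None, hours=None)
    places = gx.build_places([r], city)
    table, excluded, no_time = gx.compute_exposures({"P1": places}, city)
    assert no_time == ["P1"]
    # per-type exposure still present, weighted absent
    assert set(table.measure) == {"live_sleep"}
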