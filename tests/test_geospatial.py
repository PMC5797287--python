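"""Distance, co-location clustering, and point-in-polygon assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import geoexposure as gx
from geoexposure.geospatial import DEFAULT_THRESHOLD_M, EARTH_RADIUS_M, point_in_ring

from conftest import make_report

MERIDIAN_DEG_M = EARTH_RADIUS_M * math.pi / 180.0  # one degree of latitude


def offset_m(lat, lon, north_m=0.0, east_m=0.0):
    """Shift a coordinate by metric offsets (small-distance approximation)."""
    return (
        lat + north_m / MERIDIAN_DEG_M,
        lon + east_m / (MERIDIAN_DEG_M * math.cos(math.radians(lat))),
    )


# ---------------------------------------------------------------------------
# haversine


def test_haversine_identity_and_meridian():
    assert gx.haversine_m((39.29, -76.61), (39.29, -76.61)) == 0.0
    d = gx.haversine_m((39.0, -76.0), (40.0, -76.0))
    # closed form: one degree of meridian arc = R * pi/180
    assert d == pytest.approx(EARTH_RADIUS_M * math.pi / 180.0, abs=1e-3)
    assert round(d, 2) == 111_194.93


def test_haversine_rejects_bad_coordinates():
    with pytest.raises(ValueError):
        gx.haversine_m((95.0, 0.0), (0.0, 0.0))


@given(
    st.floats(-80, 80),
    st.floats(-179, 179),
    st.floats(-80, 80),
    st.floats(-179, 179),
)
@settings(max_examples=200, deadline=None)
def test_haversine_symmetric_nonnegative(lat1, lon1, lat2, lon2):
    p, q = (lat1, lon1), (lat2, lon2)
    d = gx.haversine_m(p, q)
    assert d >= 0.0
    assert d == gx.haversine_m(q, p)


def test_haversine_matches_law_of_cosines_oracle():
    """Independent spherical-law-of-cosines formula agrees to 1e-6 relative."""

    def slc(p, q):
        phi1, phi2 = math.radians(p[0]), math.radians(q[0])
        dlam = math.radians(q[1] - p[1])
        c = math.sin(phi1) * math.sin(phi2) + math.cos(phi1) * math.cos(phi2) * math.cos(dlam)
        return EARTH_RADIUS_M * math.acos(max(-1.0, min(1.0, c)))

    rng = np.random.default_rng(42)
    for _ in range(500):
        p = (rng.uniform(-80, 80), rng.uniform(-179, 179))
        q = (p[0] + rng.uniform(-1, 1), p[1] + rng.uniform(-1, 1))
        d1, d2 = gx.haversine_m(p, q), slc(p, q)
        if d2 > 1.0:  # law of cosines is numerically unstable near zero
            assert abs(d1 - d2) / d2 < 1e-6


# ---------------------------------------------------------------------------
# colocate


def test_identical_coordinates_merge():
    reports = [make_report(ltype="live_sleep"), make_report(ltype="socialize")]
    places = gx.colocate(reports)
    assert len(places) == 1
    assert places[0].member_types == ("live_sleep", "socialize")


def test_chain_merges_under_single_linkage_but_not_seed():
    lat, lon = 39.30, -76.61
    a = make_report(ltype="live_sleep", lat=lat, lon=lon)
    b_lat, b_lon = offset_m(lat, lon, north_m=600)
    b = make_report(ltype="inject", lat=b_lat, lon=b_lon)
    c_lat, c_lon = offset_m(lat, lon, north_m=1200)
    c = make_report(ltype="socialize", lat=c_lat, lon=c_lon)

    single = gx.colocate([a, b, c], gx.CoLocationRule(linkage="single"))
    assert len(single) == 1  # transitive closure: A-B 600, B-C 600, A-C 1200

    seed = gx.colocate([a, b, c], gx.CoLocationRule(linkage="seed"))
    assert len(seed) == 2  # C is 1200 m from seed A, so it starts a new place


def test_700m_apart_are_distinct_places():
    lat, lon = 39.30, -76.61
    a = make_report(ltype="live_sleep")
    b_lat, b_lon = offset_m(lat, lon, north_m=700)
    b = make_report(ltype="inject", lat=b_lat, lon=b_lon)
    assert len(gx.colocate([a, b])) == 2
    # 600 m is inside the 643.7376 m threshold
    c_lat, c_lon = offset_m(lat, lon, north_m=600)
    c = make_report(ltype="inject", lat=c_lat, lon=c_lon)
    assert len(gx.colocate([a, c])) == 1


def test_representative_is_max_hours_member_with_type_order_ties():
    a = make_report(ltype="live_sleep", lat=39.300, lon=-76.610)
    b = make_report(ltype="socialize", lat=39.301, lon=-76.610)
    places = gx.colocate([a, b], weekly_hours={"live_sleep": 10.0, "socialize": 50.0})
    assert places[0].representative == (39.301, -76.610)
    # tie -> fixed type order wins
    places = gx.colocate([a, b], weekly_hours={"live_sleep": 50.0, "socialize": 50.0})
    assert places[0].representative == (39.300, -76.610)
    # missing hours sort last
    places = gx.colocate([a, b], weekly_hours={"live_sleep": None, "socialize": 1.0})
    assert places[0].representative == (39.301, -76.610)


def _random_reports(rng, n):
    lat0, lon0 = 39.30, -76.61
    return [
        make_report(
            ltype=t,
            lat=lat0 + rng.uniform(-0.02, 0.02),
            lon=lon0 + rng.uniform(-0.02, 0.02),
        )
        for t in rng.permutation(gx.LOCATION_TYPES)[:n]
    ]


def _single_linkage_oracle(reports, threshold_m):
    """Brute-force transitive closure via networkx connected components."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(reports)))
    for i in range(len(reports)):
        for j in range(i + 1, len(reports)):
            d = gx.haversine_m(
                (reports[i].lat, reports[i].lon), (reports[j].lat, reports[j].lon)
            )
            if d <= threshold_m:
                g.add_edge(i, j)
    return {
        frozenset(reports[i].location_type for i in comp)
        for comp in nx.connected_components(g)
    }


def test_colocate_matches_single_linkage_oracle():
    rng = np.random.default_rng(3)
    for _ in range(300):
        reports = _random_reports(rng, int(rng.integers(1, 7)))
        places = gx.colocate(reports)
        got = {frozenset(p.member_types) for p in places}
        assert got == _single_linkage_oracle(reports, DEFAULT_THRESHOLD_M)


def test_colocate_partition_and_permutation_invariance():
    rng = np.random.default_rng(5)
    for _ in range(100):
        reports = _random_reports(rng, 6)
        places = gx.colocate(reports)
        all_types = [t for p in places for t in p.member_types]
        assert sorted(all_types) == sorted(r.location_type for r in reports)
        shuffled = list(rng.permutation(len(reports)))
        places2 = gx.colocate([reports[i] for i in shuffled])
        assert {frozenset(p.member_types) for p in places} == {
            frozenset(p.member_types) for p in places2
        }


def test_shrinking_threshold_never_merges():
    rng = np.random.default_rng(9)
    for _ in range(50):
        reports = _random_reports(rng, 6)
        big = gx.colocate(reports, gx.CoLocationRule(threshold_m=900.0))
        small = gx.colocate(reports, gx.CoLocationRule(threshold_m=450.0))
        # every small-threshold place is contained in one big-threshold place
        for sp in small:
            assert any(set(sp.member_types) <= set(bp.member_types) for bp in big)
        assert len(small) >= len(big)


def test_colocate_empty_input():
    assert gx.colocate([]) == []


# ---------------------------------------------------------------------------
# assign_area


def _centroid(ring):
    lats = [v[0] for v in ring[:-1]]
    lons = [v[1] for v in ring[:-1]]
    return sum(lats) / len(lats), sum(lons) / len(lons)


def test_centroid_assigned_to_own_area(city):
    for area_id in city.area_ids[::7]:
        assert gx.assign_area(_centroid(city.rings[area_id]), city) == area_id


def test_far_point_unassigned(city):
    assert gx.assign_area((0.0, 0.0), city) == gx.UNASSIGNED


def test_shared_boundary_resolves_to_smallest_area_id(city):
    # A000 and A001 share their east/west edge in the grid city
    ring = city.rings["A000"]
    east_lon = max(v[1] for v in ring)
    mid_lat = (min(v[0] for v in ring) + max(v[0] for v in ring)) / 2.0
    assert gx.assign_area((mid_lat, east_lon), city) == "A000"


def _winding_number_inside(lat, lon, ring):
    """Independent winding-number oracle (nonzero rule)."""
    wn = 0
    for (lat1, lon1), (lat2, lon2) in zip(ring[:-1], ring[1:]):
        if lat1 <= lat:
            if lat2 > lat:
                cross = (lon2 - lon1) * (lat - lat1) - (lat2 - lat1) * (lon - lon1)
                if cross < 0:
                    wn += 1
        else:
            if lat2 <= lat:
                cross = (lon2 - lon1) * (lat - lat1) - (lat2 - lat1) * (lon - lon1)
                if cross > 0:
                    wn -= 1
    return wn != 0


def test_point_in_ring_matches_winding_number_oracle(city):
    rng = np.random.default_rng(17)
    lats = [v[0] for ring in city.rings.values() for v in ring]
    lons = [v[1] for ring in city.rings.values() for v in ring]
    hits = 0
    for _ in range(1000):
        lat = rng.uniform(min(lats) - 0.01, max(lats) + 0.01)
        lon = rng.uniform(min(lons) - 0.01, max(lons) + 0.01)
        for ring in city.rings.values():
            expected = _winding_number_inside(lat, lon, ring)
            assert point_in_ring(lat, lon, ring) == expected
            hits += expected
    assert hits > 0  # the sample actually exercised interior points


def test_assignment_agrees_with_shapely(city):
    shapely = pytest.importorskip("shapely")
    from shapely.geometry import Point, Polygon

    polys = {a: Polygon([(lon, lat) for lat, lon in r]) for a, r in city.rings.items()}
    rng = np.random.default_rng(23)
    lats = [v[0] for ring in city.rings.values() for v in ring]
    lons = [v[1] for ring in city.rings.values() for v in ring]
    for _ in range(300):
        lat = rng.uniform(min(lats), max(lats))
        lon = rng.uniform(min(lons), max(lons))
        got = gx.assign_area((lat, lon), city)
        expected = sorted(
            a for a, poly in polys.items() if poly.covers(Point(lon, lat))
        )
        if expected:
            assert got == expected[0]
        else:
            assert got == gx.UNASSIGNED
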