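"""Geodesic distance, co-location clustering, and point-in-polygon assignment.

Two reported locations belong to the same *unique place* when they match
exactly or fall within 0.4 statute miles of each other (the survey allowed
approximate addresses for sensitive locations, so nearby coordinates denote
the same physical place).  Each unique place is then assigned to the
neighborhood polygon containing its representative coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .survey_io import LOCATION_TYPES, UNASSIGNED, AreaFrame, LocationReport

EARTH_RADIUS_M = 6_371_000.0
METERS_PER_MILE = 1_609.344
#: 0.4 statute miles, the co-location threshold.
DEFAULT_THRESHOLD_M = 0.4 * METERS_PER_MILE  # 643.7376 m exactly

_TYPE_ORDER = {t: i for i, t in enumerate(LOCATION_TYPES)}


@dataclass(frozen=True)
class CoLocationRule:
    """Distance rule deciding when two reports denote the same place.

    ``linkage`` is ``"single"`` (transitive closure over all pairs; default)
    or ``"seed"`` (each report joins the first earlier place whose seed member
    is within threshold — no chaining).
    """

    threshold_m: float = DEFAULT_THRESHOLD_M
    earth_radius_m: float = EARTH_RADIUS_M
    linkage: str = "single"

    def __post_init__(self) -> None:
        if self.threshold_m <= 0 or self.earth_radius_m <= 0:
            raise ValueError("threshold_m and earth_radius_m must be positive")
        if self.linkage not in ("single", "seed"):
            raise ValueError(f"unknown linkage {self.linkage!r}")


@dataclass
class UniquePlace:
    """A deduplicated place for one participant.

    ``member_types`` is ordered by the fixed survey order; ``member_hours``
    keeps each member type's own resolved weekly hours (``None`` if the time
    answers were missing), and ``weekly_hours`` is the place-level t_i after
    the duplicate-hours rule is applied.
    """

    participant_id: str
    place_id: str
    member_types: tuple[str, ...]
    representative: tuple[float, float]
    member_coords: dict[str, tuple[float, float]] = field(default_factory=dict)
    member_hours: dict[str, float | None] = field(default_factory=dict)
    weekly_hours: float | None = None
    area_id: str = UNASSIGNED

    @property
    def multiplicity(self) -> int:
        return len(self.member_types)


def haversine_m(
    p: tuple[float, float], q: tuple[float, float], radius: float = EARTH_RADIUS_M
) -> float:
    """Great-circle distance in meters between two (lat, lon) points in degrees."""
    for lat, lon in (p, q):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"coordinate out of range: ({lat}, {lon})")
    phi1, lam1 = math.radians(p[0]), math.radians(p[1])
    phi2, lam2 = math.radians(q[0]), math.radians(q[1])
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * radius * math.asin(min(1.0, math.sqrt(a)))


def colocate(
    reports: Sequence[LocationReport],
    rule: CoLocationRule = CoLocationRule(),
    weekly_hours: Mapping[str, float | None] | None = None,
) -> list[UniquePlace]:
    """Partition one participant's reports into unique places.

    Under single linkage, reports within ``rule.threshold_m`` of each other
    are merged transitively (union-find).  The representative coordinate is
    the member with the largest weekly hours (missing hours sort last; ties
    broken by the fixed location-type order).

    ``weekly_hours`` maps location_type -> resolved hours/week or None; when
    omitted, all hours are treated as missing and the representative falls
    back to type order.
    """
    reports = sorted(reports, key=lambda r: _TYPE_ORDER[r.location_type])
    if not reports:
        return []
    pid = reports[0].participant_id
    if any(r.participant_id != pid for r in reports):
        raise ValueError("colocate expects reports from a single participant")
    if len({r.location_type for r in reports}) != len(reports):
        raise ValueError("at most one report per location type")
    hours = dict(weekly_hours or {})

    n = len(reports)
    if rule.linkage == "single":
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                d = haversine_m(
                    (reports[i].lat, reports[i].lon),
                    (reports[j].lat, reports[j].lon),
                    rule.earth_radius_m,
                )
                if d <= rule.threshold_m:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        clusters = sorted(groups.values(), key=lambda g: min(g))
    else:  # seed linkage: join the first existing place whose seed is close enough
        clusters = []
        seeds: list[int] = []
        for i in range(n):
            for k, s in enumerate(seeds):
                d = haversine_m(
                    (reports[i].lat, reports[i].lon),
                    (reports[s].lat, reports[s].lon),
                    rule.earth_radius_m,
                )
                if d <= rule.threshold_m:
                    clusters[k].append(i)
                    break
            else:
                seeds.append(i)
                clusters.append([i])

    places: list[UniquePlace] = []
    for k, members in enumerate(clusters):
        member_reports = [reports[i] for i in members]
        types = tuple(r.location_type for r in member_reports)

        def sort_key(r: LocationReport) -> tuple[float, int]:
            h = hours.get(r.location_type)
            return (-(h if h is not None else -math.inf), _TYPE_ORDER[r.location_type])

        rep = min(member_reports, key=sort_key)
        places.append(
            UniquePlace(
                participant_id=pid,
                place_id=f"{pid}:{k}",
                member_types=types,
                representative=(rep.lat, rep.lon),
                member_coords={r.location_type: (r.lat, r.lon) for r in member_reports},
                member_hours={t: hours.get(t) for t in types},
            )
        )
    return places


def _point_on_segment(
    lat: float, lon: float, a: tuple[float, float], b: tuple[float, float], eps: float = 1e-12
) -> bool:
    (lat1, lon1), (lat2, lon2) = a, b
    cross = (lon2 - lon1) * (lat - lat1) - (lat2 - lat1) * (lon - lon1)
    if abs(cross) > eps:
        return False
    if min(lon1, lon2) - eps <= lon <= max(lon1, lon2) + eps and (
        min(lat1, lat2) - eps <= lat <= max(lat1, lat2) + eps
    ):
        return True
    return False


def point_in_ring(lat: float, lon: float, ring: Sequence[tuple[float, float]]) -> bool:
    """Ray-casting containment test in the lat/lon plane; boundary counts as inside."""
    inside = False
    for a, b in zip(ring[:-1], ring[1:]):
        if _point_on_segment(lat, lon, a, b):
            return True
        (lat1, lon1), (lat2, lon2) = a, b
        # Cast the ray in +lon direction; standard even-odd crossing rule.
        if (lat1 > lat) != (lat2 > lat):
            lon_cross = lon1 + (lat - lat1) * (lon2 - lon1) / (lat2 - lat1)
            if lon < lon_cross:
                inside = not inside
    return inside


def assign_area(point: tuple[float, float], areas: AreaFrame) -> str:
    """Containing area of a (lat, lon) point, or UNASSIGNED.

    Areas are probed in lexicographic area_id order, so a point on a shared
    boundary deterministically resolves to the smallest id.
    """
    lat, lon = point
    for area_id in areas.area_ids:
        ring = areas.rings[area_id]
        # cheap bounding-box reject before the full test
        lats = [v[0] for v in ring]
        lons = [v[1] for v in ring]
        if lat < min(lats) or lat > max(lats) or lon < min(lons) or lon > max(lons):
            continue
        if point_in_ring(lat, lon, ring):
            return area_id
    return UNASSIGNED


def assign_places(places: Iterable[UniquePlace], areas: AreaFrame) -> None:
    """Assign every place's representative coordinate to an area, in place."""
    for place in places:
        place.area_id = assign_area(place.representative, areas)
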