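"""Time-use resolution, time fractions, and neighborhood exposure measures.

For a participant with unique places i = 1..m carrying weekly hours t_i, the
time fraction at place i is w_i = t_i / sum_j t_j, and the time-weighted
neighborhood exposure for indicator X is

    E = sum_i w_i * X_c(i)

where c(i) is the area containing place i.  Alongside the weighted measure,
each of the six location types defines a conventional single-location
exposure: E_type = X of the area containing that type's place.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .geospatial import UniquePlace, assign_places
from .survey_io import (
    LESS_THAN_ONE,
    LOCATION_TYPES,
    UNASSIGNED,
    AreaFrame,
    LocationReport,
)

log = logging.getLogger(__name__)

#: Measure label for the time-weighted exposure, alongside the 6 types.
WEIGHTED = "weighted"
MEASURES: tuple[str, ...] = LOCATION_TYPES + (WEIGHTED,)

#: Flag for participants with no usable time data (no fractions emitted).
NO_TIME_DATA = "NO_TIME_DATA"


@dataclass(frozen=True)
class TimeUsePolicy:
    """Numeric resolution of time-use answers.

    The survey's "<1 day" / "<1 hour" options are open intervals; they resolve
    to their midpoint (0.5) by default.  ``duplicate_hours_rule`` reconciles
    differing hours reported for co-located types ("max" keeps the fullest
    estimate of time at the physical place without double counting; "mean"
    averages).  ``unassigned_policy`` handles places outside every area:
    "drop_participant" removes the participant from all exposure analyses,
    "renormalize" re-weights over the assigned places.
    """

    less_than_one_day: float = 0.5
    less_than_one_hour: float = 0.5
    missing_policy: str = "exclude_location"
    duplicate_hours_rule: str = "max"
    unassigned_policy: str = "drop_participant"

    def __post_init__(self) -> None:
        if not (0.0 < self.less_than_one_day < 1.0):
            raise ValueError("less_than_one_day must be in (0, 1)")
        if not (0.0 < self.less_than_one_hour < 1.0):
            raise ValueError("less_than_one_hour must be in (0, 1)")
        if self.missing_policy not in ("exclude_location", "zero"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        if self.duplicate_hours_rule not in ("max", "mean"):
            raise ValueError(f"unknown duplicate_hours_rule {self.duplicate_hours_rule!r}")
        if self.unassigned_policy not in ("drop_participant", "renormalize"):
            raise ValueError(f"unknown unassigned_policy {self.unassigned_policy!r}")


def weekly_hours(
    days_per_week: int | str | None,
    hours_per_day: int | str | None,
    policy: TimeUsePolicy = TimeUsePolicy(),
) -> float | None:
    """Resolve the two time answers to hours/week, or None if either is missing."""
    if days_per_week is None or hours_per_day is None:
        if policy.missing_policy == "zero":
            return 0.0
        return None
    if days_per_week == LESS_THAN_ONE:
        days = policy.less_than_one_day
    else:
        days = float(days_per_week)
        if not (0 <= days <= 7):
            raise ValueError(f"days_per_week out of range: {days_per_week}")
    if hours_per_day == LESS_THAN_ONE:
        hours = policy.less_than_one_hour
    else:
        hours = float(hours_per_day)
        if not (0 <= hours <= 24):
            raise ValueError(f"hours_per_day out of range: {hours_per_day}")
    return days * hours


def resolve_place_hours(
    places: Iterable[UniquePlace], policy: TimeUsePolicy = TimeUsePolicy()
) -> None:
    """Set each place's t_i from its members' hours via the duplicate rule."""
    for place in places:
        known = [h for h in place.member_hours.values() if h is not None]
        if not known:
            place.weekly_hours = None
        elif policy.duplicate_hours_rule == "max":
            place.weekly_hours = max(known)
        else:
            place.weekly_hours = sum(known) / len(known)


def build_places(
    reports: Sequence[LocationReport],
    areas: AreaFrame | None = None,
    policy: TimeUsePolicy = TimeUsePolicy(),
    rule=None,
) -> list[UniquePlace]:
    """Full per-participant place construction: hours, clustering, assignment."""
    from .geospatial import CoLocationRule, colocate

    if rule is None:
        rule = CoLocationRule()
    hours = {
        r.location_type: weekly_hours(r.days_per_week, r.hours_per_day, policy)
        for r in reports
    }
    places = colocate(reports, rule, weekly_hours=hours)
    resolve_place_hours(places, policy)
    total = sum(p.weekly_hours or 0.0 for p in places)
    if total > 168.0:
        log.warning(
            "participant %s reports %.1f h/week in total (> 168)",
            places[0].participant_id if places else "?",
            total,
        )
    if areas is not None:
        assign_places(places, areas)
    return places


def time_fractions(places: Sequence[UniquePlace]) -> dict[str, float]:
    """Per-place time fractions w_i = t_i / sum_j t_j.

    Places with missing t_i are excluded; zero-time places get w = 0.  If no
    place has positive time, the participant has no usable time data and an
    empty mapping is returned (flagged NO_TIME_DATA upstream).
    """
    usable = [p for p in places if p.weekly_hours is not None]
    total = sum(p.weekly_hours for p in usable)
    if total <= 0.0:
        return {}
    return {p.place_id: p.weekly_hours / total for p in usable}


def weighted_exposure(
    fractions: Mapping[str, float],
    assignments: Mapping[str, str],
    areas: AreaFrame,
    indicator_name: str,
) -> float:
    """E = sum_i w_i * X_c(i) over a participant's places."""
    if indicator_name not in areas.indicator_names:
        raise KeyError(f"unknown indicator {indicator_name!r}")
    e = 0.0
    for place_id, w in fractions.items():
        area = assignments[place_id]
        if area == UNASSIGNED:
            raise ValueError(f"place {place_id} is unassigned; apply a policy first")
        e += w * areas.value(area, indicator_name)
    return e


def per_type_exposure(
    places: Sequence[UniquePlace], areas: AreaFrame, indicator_name: str
) -> dict[str, float]:
    """Single-location exposure per reported type: X of the type's area.

    Types whose place is unassigned yield no entry; types the participant did
    not report naturally produce none either.
    """
    out: dict[str, float] = {}
    for place in places:
        if place.area_id == UNASSIGNED:
            continue
        x = areas.value(place.area_id, indicator_name)
        for t in place.member_types:
            out[t] = x
    return out


def percent_time_by_type(places: Sequence[UniquePlace]) -> dict[str, float]:
    """Share of the participant's time for each reported type.

    The share of a type is the w of the unique place containing it, so types
    sharing a place report the same share and shares may sum over 1.
    """
    fractions = time_fractions(places)
    shares: dict[str, float] = {}
    for place in places:
        if place.place_id not in fractions:
            continue
        for t in place.member_types:
            shares[t] = fractions[place.place_id]
    return shares


def compute_exposures(
    places_by_participant: Mapping[str, Sequence[UniquePlace]],
    areas: AreaFrame,
    indicators: Sequence[str] | None = None,
    policy: TimeUsePolicy = TimeUsePolicy(),
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Exposure table over all participants, measures and indicators.

    Returns (exposures, excluded_out_of_area, no_time_data):

    * ``exposures``: DataFrame with columns participant_id, measure,
      indicator, value — one row per (participant, available measure,
      indicator).  The six per-type measures require only an assigned place;
      the weighted measure additionally requires usable time data.
    * ``excluded_out_of_area``: participants dropped entirely because a
      reported place lies outside every area (default policy).
    * ``no_time_data``: retained participants lacking any weighted exposure.
    """
    if indicators is None:
        indicators = areas.indicator_names
    rows = []
    excluded: list[str] = []
    no_time: list[str] = []
    for pid, places in places_by_participant.items():
        places = list(places)
        if policy.unassigned_policy == "drop_participant":
            if any(p.area_id == UNASSIGNED for p in places):
                excluded.append(pid)
                continue
            included = places
        else:
            included = [p for p in places if p.area_id != UNASSIGNED]
            if not included:
                excluded.append(pid)
                continue
        fractions = time_fractions(included)
        if not fractions:
            no_time.append(pid)
        assignments = {p.place_id: p.area_id for p in included}
        type_area = {t: p.area_id for p in included for t in p.member_types}
        for name in indicators:
            for ltype, area in type_area.items():
                rows.append((pid, ltype, name, areas.value(area, name)))
            if fractions:
                e = weighted_exposure(fractions, assignments, areas, name)
                rows.append((pid, WEIGHTED, name, e))
    frame = pd.DataFrame(
        rows, columns=["participant_id", "measure", "indicator", "value"]
    )
    return frame, excluded, no_time
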