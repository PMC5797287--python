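"""Reading, validation and writing of survey, polygon and indicator files.

The survey instrument asks each participant six location questions — where
they live/sleep, inject, spend most time, work/earn money, socialize, and
were recruited — each with two time-use follow-ups (days per week, hours per
day).  This module turns the three on-disk artifacts (survey CSV, area
GeoJSON, indicator CSV) into the in-memory model the rest of the pipeline
consumes, and writes every result table back out as delimited text.

I/O is deliberately lossless: the "<1 day"/"<1 hour" answers are kept as a
distinct token here and resolved to numbers only in :mod:`geoexposure.timeuse`,
and missing time answers are retained so a location can still enter the
overlap tables even when it cannot be weighted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

# The closed set of location types, in fixed survey order.  This order is
# also the deterministic tie-break order used throughout the pipeline.
LOCATION_TYPES: tuple[str, ...] = (
    "live_sleep",
    "inject",
    "spend_most_time",
    "work_earn",
    "socialize",
    "recruited",
)

#: Token preserved for "<1 day" / "<1 hour" answers.
LESS_THAN_ONE = "<1"

#: Sentinel area id for places outside every polygon.
UNASSIGNED = "UNASSIGNED"

# Tokens (case-insensitive) that map to a missing time answer.
_MISSING_TOKENS = {"", "na", "n/a", "not applicable", "decline", "decline to answer"}

SURVEY_COLUMNS = (
    "participant_id",
    "location_type",
    "lat",
    "lon",
    "days_per_week",
    "hours_per_day",
)

# Row-rejection reason codes.
OUT_OF_RANGE_COORD = "OUT_OF_RANGE_COORD"
UNKNOWN_LOCATION_TYPE = "UNKNOWN_LOCATION_TYPE"
DUPLICATE_REPORT = "DUPLICATE_REPORT"
BAD_TIME_VALUE = "BAD_TIME_VALUE"
BAD_COORD = "BAD_COORD"
MISSING_FIELD = "MISSING_FIELD"


class AreaMismatchError(ValueError):
    """Polygon file and indicator file disagree on the set of area ids."""

    def __init__(self, missing_indicator: Sequence[str], missing_polygon: Sequence[str]):
        self.missing_indicator = list(missing_indicator)
        self.missing_polygon = list(missing_polygon)
        parts = []
        if self.missing_indicator:
            parts.append(f"MISSING_INDICATOR for areas {self.missing_indicator}")
        if self.missing_polygon:
            parts.append(f"MISSING_POLYGON for areas {self.missing_polygon}")
        super().__init__("; ".join(parts))


@dataclass(frozen=True)
class LocationReport:
    """One participant's answer to one location question.

    ``days_per_week`` / ``hours_per_day`` are either an in-range ``int``,
    the :data:`LESS_THAN_ONE` token, or ``None`` (not applicable / declined).
    """

    participant_id: str
    location_type: str
    lat: float
    lon: float
    days_per_week: int | str | None = None
    hours_per_day: int | str | None = None

    def __post_init__(self) -> None:
        if self.location_type not in LOCATION_TYPES:
            raise ValueError(f"unknown location_type {self.location_type!r}")
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"coordinate out of range: ({self.lat}, {self.lon})")


@dataclass
class ValidationReport:
    """Accounting of rows read vs accepted; ``rejects`` holds (row index, reason)."""

    n_rows_read: int = 0
    n_rows_accepted: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def check(self) -> None:
        assert self.n_rows_accepted + len(self.rejects) == self.n_rows_read


@dataclass
class AreaFrame:
    """Area polygons plus their indicator values.

    ``rings`` maps area_id to a closed ring of (lat, lon) vertices (first ==
    last, >= 4 vertices, nonzero area).  ``indicators`` is a DataFrame indexed
    by area_id with one column per indicator.
    """

    rings: dict[str, list[tuple[float, float]]]
    indicators: pd.DataFrame

    def __post_init__(self) -> None:
        for area_id, ring in self.rings.items():
            _validate_ring(area_id, ring)
        poly_ids = set(self.rings)
        ind_ids = set(self.indicators.index.astype(str))
        if poly_ids != ind_ids:
            raise AreaMismatchError(
                sorted(poly_ids - ind_ids), sorted(ind_ids - poly_ids)
            )

    @property
    def area_ids(self) -> list[str]:
        return sorted(self.rings)

    @property
    def indicator_names(self) -> list[str]:
        return list(self.indicators.columns)

    def value(self, area_id: str, indicator_name: str) -> float:
        if indicator_name not in self.indicators.columns:
            raise KeyError(f"unknown indicator {indicator_name!r}")
        return float(self.indicators.at[area_id, indicator_name])


def _validate_ring(area_id: str, ring: Sequence[tuple[float, float]]) -> None:
    if len(ring) < 4:
        raise ValueError(f"area {area_id}: ring has fewer than 4 vertices")
    if ring[0] != ring[-1]:
        raise ValueError(f"area {area_id}: ring is not closed")
    if abs(_shoelace(ring)) == 0.0:
        raise ValueError(f"area {area_id}: ring has zero area")


def _shoelace(ring: Sequence[tuple[float, float]]) -> float:
    # Signed area in degree^2; only used for the degeneracy check.
    s = 0.0
    for (lat1, lon1), (lat2, lon2) in zip(ring[:-1], ring[1:]):
        s += lon1 * lat2 - lon2 * lat1
    return 0.5 * s


def _parse_time_answer(raw: object) -> tuple[bool, int | str | None]:
    """Parse a days/hours cell.  Returns (ok, value); range is checked later."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return True, None
    text = str(raw).strip()
    if text.lower() in _MISSING_TOKENS:
        return True, None
    if text == LESS_THAN_ONE or text.lower() in {"<1 day", "<1 hour", "lt1"}:
        return True, LESS_THAN_ONE
    try:
        value = float(text)
    except ValueError:
        return False, None
    if value != int(value):
        return False, None
    return True, int(value)


def read_survey(
    path: str | Path,
    rename_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> tuple[list[LocationReport], ValidationReport]:
    """Read a survey CSV into validated :class:`LocationReport` rows.

    ``rename_map`` maps actual file column names to the canonical ones in
    :data:`SURVEY_COLUMNS`.  Malformed rows are rejected individually with a
    reason code; an unreadable file or missing required column is fatal.
    """
    df = pd.read_csv(path, dtype=str, sep=delimiter, keep_default_na=False)
    if rename_map:
        df = df.rename(columns=dict(rename_map))
    missing_cols = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"survey file missing required columns: {missing_cols}")

    report = ValidationReport(n_rows_read=len(df))
    accepted: list[LocationReport] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        pid = str(getattr(row, "participant_id")).strip()
        ltype = str(getattr(row, "location_type")).strip()
        if not pid or not ltype:
            report.rejects.append((idx, MISSING_FIELD))
            continue
        if ltype not in LOCATION_TYPES:
            report.rejects.append((idx, UNKNOWN_LOCATION_TYPE))
            continue
        try:
            lat = float(getattr(row, "lat"))
            lon = float(getattr(row, "lon"))
        except (TypeError, ValueError):
            report.rejects.append((idx, BAD_COORD))
            continue
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            report.rejects.append((idx, OUT_OF_RANGE_COORD))
            continue
        ok_d, days = _parse_time_answer(getattr(row, "days_per_week"))
        ok_h, hours = _parse_time_answer(getattr(row, "hours_per_day"))
        if not ok_d or not ok_h:
            report.rejects.append((idx, BAD_TIME_VALUE))
            continue
        if isinstance(days, int) and not (0 <= days <= 7):
            report.rejects.append((idx, BAD_TIME_VALUE))
            continue
        if isinstance(hours, int) and not (0 <= hours <= 24):
            report.rejects.append((idx, BAD_TIME_VALUE))
            continue
        key = (pid, ltype)
        if key in seen:
            report.rejects.append((idx, DUPLICATE_REPORT))
            continue
        seen.add(key)
        accepted.append(
            LocationReport(
                participant_id=pid,
                location_type=ltype,
                lat=lat,
                lon=lon,
                days_per_week=days,
                hours_per_day=hours,
            )
        )
    report.n_rows_accepted = len(accepted)
    report.check()
    return accepted, report


def read_areas(polygon_path: str | Path, indicator_path: str | Path) -> AreaFrame:
    """Read a GeoJSON FeatureCollection plus an indicator CSV into an AreaFrame.

    GeoJSON stores coordinates as (lon, lat); they are converted to the
    internal (lat, lon) convention here.  Only the first (exterior) ring of
    each Polygon feature is used.  An area present in one file but not the
    other is fatal (:class:`AreaMismatchError` naming the offending ids).
    """
    with open(polygon_path) as fh:
        geo = json.load(fh)
    if geo.get("type") != "FeatureCollection":
        raise ValueError("polygon file is not a GeoJSON FeatureCollection")
    rings: dict[str, list[tuple[float, float]]] = {}
    for feature in geo.get("features", []):
        props = feature.get("properties") or {}
        area_id = props.get("area_id")
        if area_id is None:
            raise ValueError("polygon feature lacks an 'area_id' property")
        geom = feature.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValueError(f"area {area_id}: geometry is not a Polygon")
        exterior = geom["coordinates"][0]
        ring = [(float(lat), float(lon)) for lon, lat in exterior]
        _validate_ring(str(area_id), ring)
        rings[str(area_id)] = ring

    indicators = pd.read_csv(indicator_path)
    if "area_id" not in indicators.columns:
        raise ValueError("indicator file missing 'area_id' column")
    indicators["area_id"] = indicators["area_id"].astype(str)
    indicators = indicators.set_index("area_id")
    indicators = indicators.astype(float)
    return AreaFrame(rings=rings, indicators=indicators)


def write_areas(
    frame: AreaFrame, polygon_path: str | Path, indicator_path: str | Path
) -> None:
    """Write an AreaFrame back to GeoJSON + indicator CSV (inverse of read_areas)."""
    features = []
    for area_id in frame.area_ids:
        ring = frame.rings[area_id]
        features.append(
            {
                "type": "Feature",
                "properties": {"area_id": area_id},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[lon, lat] for lat, lon in ring]],
                },
            }
        )
    with open(polygon_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    out = frame.indicators.reset_index()
    out.to_csv(indicator_path, index=False)


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as CSV with header; round-trips to full precision."""
    rows.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so write_table -> read_table is bit-exact for floats
    return pd.read_csv(path, float_precision="round_trip")


def reports_to_frame(reports: Iterable[LocationReport]) -> pd.DataFrame:
    """Tabular view of reports (used by the simulator's CSV writer)."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "location_type": r.location_type,
                "lat": r.lat,
                "lon": r.lon,
                "days_per_week": "" if r.days_per_week is None else r.days_per_week,
                "hours_per_day": "" if r.hours_per_day is None else r.hours_per_day,
            }
            for r in reports
        ],
        columns=list(SURVEY_COLUMNS),
    )
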