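"""Synthetic city and survey-cohort generator.

Real multi-location survey data of this kind cannot be shared (the locations
are identifying), so every stage of the pipeline is exercised against a
synthetic world instead: a grid city of ~55 contiguous rectangular areas
carrying spatially structured indicators, and a cohort whose statistical
structure matches what such surveys report —

* six location types with realistic applicability (everyone has a home;
  roughly 22% provide an injection location, 30% a work location, 78% a
  socializing location),
* heavy concentration of time at home (median share ~0.89),
* substantial co-location across types (about half of unique places serve a
  single type), with small jitter between co-located reports,
* type-specific spatial bias (injection and recruitment places sit in
  higher-disorder areas, work places in lower-disorder areas), and
* a small fraction of participants reporting one location outside the city.

The generator emits both the survey CSV the pipeline reads and a ground-truth
sidecar (true place clusters, true areas, true weighted exposures) so that
recovery can be checked exactly.  Construction margins guarantee exact
cluster recovery: members jitter at most ``jitter_frac`` x threshold around
their place's seed coordinate while distinct seeds stay at least
``min_sep_frac`` x threshold apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geospatial import DEFAULT_THRESHOLD_M
from .survey_io import (
    LESS_THAN_ONE,
    LOCATION_TYPES,
    UNASSIGNED,
    AreaFrame,
    LocationReport,
    reports_to_frame,
    write_areas,
    write_table,
)
from .timeuse import TimeUsePolicy, weekly_hours

# meters per degree of latitude on the R = 6,371 km sphere
_M_PER_DEG = 6_371_000.0 * math.pi / 180.0

# anchor priority: the first provided type anchors the participant's home place
_ANCHOR_PRIORITY = (
    "live_sleep",
    "spend_most_time",
    "socialize",
    "recruited",
    "inject",
    "work_earn",
)


@dataclass(frozen=True)
class IndicatorSpec:
    """One synthetic neighborhood indicator.

    ``pattern`` is "gradient" (monotone along the grid's east-west axis),
    "hotspot" (Gaussian bump around a random cell), or "uniform" (iid noise
    around the base value).  ``effect`` scales the spatial structure.
    """

    name: str
    pattern: str = "gradient"
    base: float = 0.0
    effect: float = 1.0

    def __post_init__(self) -> None:
        if self.pattern not in ("gradient", "hotspot", "uniform"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


DEFAULT_INDICATORS = (
    IndicatorSpec("violent_crime_rate", "gradient", base=30.0, effect=40.0),
    IndicatorSpec("vacant_housing_pct", "hotspot", base=8.0, effect=20.0),
    IndicatorSpec("median_income_k", "gradient", base=75.0, effect=-45.0),
)


@dataclass(frozen=True)
class CityConfig:
    """Grid-city parameters: a 7x8 grid trimmed to 55 areas by default."""

    seed: int = 0
    n_rows: int = 7
    n_cols: int = 8
    n_areas: int = 55
    cell_km: float = 1.0
    origin: tuple[float, float] = (39.20, -76.70)
    indicators: tuple[IndicatorSpec, ...] = DEFAULT_INDICATORS

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols < 2 or self.cell_km <= 0:
            raise ValueError("grid must have >= 2 cells and positive cell size")
        if not (2 <= self.n_areas <= self.n_rows * self.n_cols):
            raise ValueError("n_areas must be between 2 and n_rows * n_cols")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort parameters; defaults state the emulated survey's conditions."""

    seed: int = 0
    n_participants: int = 547
    #: per-type probability of providing that location (live_sleep etc. from
    #: observed applicability 540/547, 534/547, 538/547; inject/work/socialize
    #: rounded applicability rates)
    p_provide: dict[str, float] = field(
        default_factory=lambda: {
            "live_sleep": 540 / 547,
            "inject": 0.22,
            "spend_most_time": 534 / 547,
            "work_earn": 0.30,
            "socialize": 0.78,
            "recruited": 538 / 547,
        }
    )
    #: target median share of time at the home place
    home_time_share: float = 0.89
    #: per-type probability that the type re-uses an existing place
    colocation_probs: dict[str, float] = field(
        default_factory=lambda: {
            "spend_most_time": 0.87,
            "inject": 0.78,
            "socialize": 0.62,
            "work_earn": 0.35,
            "recruited": 0.45,
        }
    )
    #: per-type spatial bias, in SD units of the bias indicator: area choice
    #: weights are proportional to exp(bias * z_area)
    type_area_bias: dict[str, float] = field(
        default_factory=lambda: {
            "inject": 1.5,
            "recruited": 0.75,
            "work_earn": -1.5,
        }
    )
    #: indicator steering type_area_bias (default: first city indicator)
    bias_indicator: str | None = None
    out_of_area_rate: float = 13 / 547
    jitter_frac: float = 0.25
    min_sep_frac: float = 2.0
    threshold_m: float = DEFAULT_THRESHOLD_M
    #: probability that a co-located member's time answers are missing
    missing_prob: float = 0.03
    #: probability of a "<1 day" answer for low-time distinct places
    lt_day_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name, p in {
            **self.p_provide,
            **self.colocation_probs,
            "out_of_area_rate": self.out_of_area_rate,
        }.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {name} out of [0, 1]: {p}")
        if self.jitter_frac > 0.5 or self.min_sep_frac - 2.0 * self.jitter_frac <= 1.0:
            # 2*jitter <= threshold keeps clusters intact; min_sep - 2*jitter >
            # threshold keeps distinct places separate -> exact recovery
            raise ValueError("jitter/min_sep margins do not guarantee recovery")


@dataclass
class CohortData:
    """Generated survey plus ground truth."""

    reports: list[LocationReport]
    truth_places: pd.DataFrame
    truth_exposure: pd.DataFrame
    truth_participants: pd.DataFrame

    @property
    def survey(self) -> pd.DataFrame:
        return reports_to_frame(self.reports)


# ---------------------------------------------------------------------------
# city


def generate_city(config: CityConfig = CityConfig()) -> AreaFrame:
    """Build the grid city: closed rectangular rings tiling the grid,
    indicator values following each spec's spatial pattern."""
    rng = np.random.default_rng(config.seed)
    lat0, lon0 = config.origin
    dlat = config.cell_km * 1000.0 / _M_PER_DEG
    mid_lat = lat0 + config.n_rows * dlat / 2.0
    dlon = config.cell_km * 1000.0 / (_M_PER_DEG * math.cos(math.radians(mid_lat)))

    cells = [
        (r, c) for r in range(config.n_rows) for c in range(config.n_cols)
    ][: config.n_areas]
    rings: dict[str, list[tuple[float, float]]] = {}
    for idx, (r, c) in enumerate(cells):
        south, west = lat0 + r * dlat, lon0 + c * dlon
        north, east = south + dlat, west + dlon
        rings[f"A{idx:03d}"] = [
            (south, west),
            (south, east),
            (north, east),
            (north, west),
            (south, west),
        ]

    values: dict[str, list[float]] = {}
    for spec in config.indicators:
        if spec.pattern == "gradient":
            denom = max(config.n_cols - 1, 1)
            vals = [spec.base + spec.effect * (c / denom) for _, c in cells]
        elif spec.pattern == "hotspot":
            rc = rng.integers(0, config.n_rows)
            cc = rng.integers(0, config.n_cols)
            sigma = max(config.n_rows, config.n_cols) / 4.0
            vals = [
                spec.base
                + spec.effect
                * math.exp(-((r - rc) ** 2 + (c - cc) ** 2) / (2.0 * sigma**2))
                for r, c in cells
            ]
        else:  # uniform
            vals = list(
                spec.base + rng.uniform(-spec.effect, spec.effect, size=len(cells))
            )
        values[spec.name] = vals
    indicators = pd.DataFrame(values, index=[f"A{i:03d}" for i in range(len(cells))])
    indicators.index.name = "area_id"
    return AreaFrame(rings=rings, indicators=indicators)


def write_city(city: AreaFrame, geojson_path: str | Path, indicator_path: str | Path) -> None:
    write_areas(city, geojson_path, indicator_path)


# ---------------------------------------------------------------------------
# cohort


def _area_weights(city: AreaFrame, bias_indicator: str, bias: float) -> np.ndarray:
    x = city.indicators[bias_indicator].to_numpy(dtype=float)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    w = np.exp(bias * z)
    return w / w.sum()


def _cell_bounds(ring: Sequence[tuple[float, float]]) -> tuple[float, float, float, float]:
    lats = [v[0] for v in ring]
    lons = [v[1] for v in ring]
    return min(lats), max(lats), min(lons), max(lons)


def _beta_a_for_target(median: float, p_all_home: float) -> float:
    """Shape a of Beta(a, 1) so the cohort's realized median home share hits
    the target, given the fraction of participants whose share is exactly 1.

    P(share <= m) = (1 - p0) * m^a must equal 0.5; closed form below.  If the
    all-home mass alone exceeds 0.5 the target is unreachable and the
    unconditional solution is used.
    """
    if p_all_home >= 0.45:
        p_all_home = 0.0
    return math.log(0.5 / (1.0 - p_all_home)) / math.log(median)


def generate_cohort(city: AreaFrame, config: CohortConfig = CohortConfig()) -> CohortData:
    """Generate a survey cohort against ``city`` with known ground truth."""
    rng = np.random.default_rng(config.seed)
    bias_indicator = config.bias_indicator or city.indicator_names[0]
    if bias_indicator not in city.indicator_names:
        raise KeyError(f"unknown bias indicator {bias_indicator!r}")
    area_ids = city.area_ids
    bounds = {a: _cell_bounds(city.rings[a]) for a in area_ids}

    jitter_max_m = config.jitter_frac * config.threshold_m
    min_sep_m = config.min_sep_frac * config.threshold_m
    margin_lat = 1.1 * jitter_max_m / _M_PER_DEG
    mid_lat = float(np.mean([b[0] for b in bounds.values()]))
    cos_lat = math.cos(math.radians(mid_lat))
    margin_lon = margin_lat / cos_lat

    weights_cache: dict[float, np.ndarray] = {}

    def area_choice(bias: float) -> str:
        if bias not in weights_cache:
            weights_cache[bias] = _area_weights(city, bias_indicator, bias)
        return area_ids[rng.choice(len(area_ids), p=weights_cache[bias])]

    # ---- pass 1: structure (provided types, reuse decisions) --------------
    structures = []
    for i in range(config.n_participants):
        provided = [
            t for t in LOCATION_TYPES if rng.random() < config.p_provide.get(t, 1.0)
        ]
        if not provided:
            provided = ["recruited"]
        anchor = next(t for t in _ANCHOR_PRIORITY if t in provided)
        # reuse[t] is the index of the existing place the type joins, or -1
        reuse: dict[str, int] = {}
        n_places = 1
        for t in provided:
            if t == anchor:
                continue
            if rng.random() < config.colocation_probs.get(t, 0.5):
                reuse[t] = int(rng.integers(0, n_places))
            else:
                reuse[t] = -1
                n_places += 1
        structures.append((provided, anchor, reuse, n_places))

    with_home = [s for s in structures if "live_sleep" in s[0]]
    p_all_home = (
        sum(1 for s in with_home if s[3] == 1) / len(with_home) if with_home else 0.0
    )
    beta_a = _beta_a_for_target(config.home_time_share, p_all_home)

    # ---- pass 2: coordinates and time answers -----------------------------
    policy = TimeUsePolicy()
    reports: list[LocationReport] = []
    place_rows = []
    participant_rows = []
    exposure_rows = []

    for i, (provided, anchor, reuse, n_places) in enumerate(structures):
        pid = f"P{i:04d}"
        out_of_area = rng.random() < config.out_of_area_rate
        out_place = int(rng.integers(0, n_places)) if out_of_area else -1

        # seed coordinates for each distinct place
        seeds: list[tuple[float, float]] = []
        seed_area: list[str] = []
        order: list[str] = [anchor] + [t for t in provided if reuse.get(t) == -1]
        for j, t in enumerate(order):
            if j == out_place:
                # well south-west of the whole city: outside every polygon
                lat = min(b[0] for b in bounds.values()) - 0.7 - rng.uniform(0.0, 0.2)
                lon = min(b[2] for b in bounds.values()) - 0.7 - rng.uniform(0.0, 0.2)
                seeds.append((lat, lon))
                seed_area.append(UNASSIGNED)
                continue
            bias = config.type_area_bias.get(t, 0.0)
            for _attempt in range(100):
                area = area_choice(bias)
                lo_lat, hi_lat, lo_lon, hi_lon = bounds[area]
                lat = rng.uniform(lo_lat + margin_lat, hi_lat - margin_lat)
                lon = rng.uniform(lo_lon + margin_lon, hi_lon - margin_lon)
                ok = all(
                    _approx_dist_m(lat, lon, s[0], s[1], cos_lat) >= min_sep_m
                    for s in seeds
                )
                if ok:
                    break
            else:
                raise RuntimeError(
                    f"could not place a location >= {min_sep_m:.0f} m from "
                    f"existing places for participant {pid}"
                )
            seeds.append((lat, lon))
            seed_area.append(area)

        # map each type to its place index
        place_of_type: dict[str, int] = {anchor: 0}
        next_new = 1
        for t in provided:
            if t == anchor:
                continue
            k = reuse[t]
            if k == -1:
                place_of_type[t] = next_new
                next_new += 1
            else:
                place_of_type[t] = k

        # time answers: anchor gets the home block, distinct places split the rest
        anchor_hours = int(np.clip(round(rng.normal(16.0, 3.0)), 8, 24))
        anchor_days = 7
        h_home = float(anchor_days * anchor_hours)
        n_distinct = n_places - 1
        answers: dict[int, tuple[int | str, int | str]] = {0: (anchor_days, anchor_hours)}
        if n_distinct > 0:
            f = float(rng.beta(beta_a, 1.0))
            f = min(max(f, 0.30), 0.995)
            t_other = h_home * (1.0 - f) / f
            splits = (
                rng.dirichlet(np.ones(n_distinct)) if n_distinct > 1 else np.array([1.0])
            )
            for j in range(1, n_places):
                target = t_other * float(splits[j - 1])
                if target < 6.0 and rng.random() < config.lt_day_prob:
                    days: int | str = LESS_THAN_ONE
                    hours: int | str = int(np.clip(round(target / 0.5), 1, 24))
                else:
                    days = int(rng.integers(1, 8))
                    raw = target / days
                    if raw < 0.75:
                        hours = LESS_THAN_ONE
                    else:
                        hours = int(np.clip(round(raw), 1, 24))
                answers[j] = (days, hours)

        # emit reports in survey order; co-located members copy the place's
        # primary answers (occasionally missing)
        member_coords: dict[int, tuple[float, float]] = {}
        for t in LOCATION_TYPES:
            if t not in place_of_type:
                continue
            j = place_of_type[t]
            slat, slon = seeds[j]
            first_member = j not in member_coords
            if first_member:
                lat, lon = slat, slon
                member_coords[j] = (lat, lon)
            elif rng.random() < 0.5:
                # exact coordinate match with the place's first member
                lat, lon = member_coords[j]
            else:
                # jitter within the recovery margin around the seed
                d = rng.uniform(0.0, jitter_max_m)
                theta = rng.uniform(0.0, 2.0 * math.pi)
                lat = slat + d * math.cos(theta) / _M_PER_DEG
                lon = slon + d * math.sin(theta) / (_M_PER_DEG * cos_lat)
            days, hours = answers[j]
            # only non-primary members may go missing, so the place's t_i
            # (max over members) always matches the sidecar truth
            if not first_member and rng.random() < config.missing_prob:
                days, hours = None, None  # type: ignore[assignment]
            reports.append(
                LocationReport(
                    participant_id=pid,
                    location_type=t,
                    lat=round(lat, 6),
                    lon=round(lon, 6),
                    days_per_week=days,
                    hours_per_day=hours,
                )
            )

        # ---- ground truth -------------------------------------------------
        t_resolved = {
            j: weekly_hours(*answers[j], policy) for j in range(n_places)
        }
        total = sum(v for v in t_resolved.values() if v is not None)
        types_of_place: dict[int, list[str]] = {}
        for t in provided:
            types_of_place.setdefault(place_of_type[t], []).append(t)
        for j in range(n_places):
            place_rows.append(
                {
                    "participant_id": pid,
                    "true_place": f"{pid}:T{j}",
                    "member_types": "|".join(
                        t for t in LOCATION_TYPES if t in types_of_place.get(j, [])
                    ),
                    "seed_lat": seeds[j][0],
                    "seed_lon": seeds[j][1],
                    "area_id": seed_area[j],
                    "weekly_hours": t_resolved[j],
                }
            )
        home_share = math.nan
        if "live_sleep" in place_of_type and total > 0:
            jh = place_of_type["live_sleep"]
            if t_resolved[jh] is not None:
                home_share = t_resolved[jh] / total
        participant_rows.append(
            {
                "participant_id": pid,
                "n_places": n_places,
                "home_share": home_share,
                "out_of_area": out_of_area,
            }
        )
        for name in city.indicator_names:
            if out_of_area or total <= 0:
                value = math.nan
            else:
                value = sum(
                    (t_resolved[j] / total) * city.value(seed_area[j], name)
                    for j in range(n_places)
                    if t_resolved[j] is not None
                )
            exposure_rows.append(
                {"participant_id": pid, "indicator": name, "weighted": value}
            )

    return CohortData(
        reports=reports,
        truth_places=pd.DataFrame(place_rows),
        truth_exposure=pd.DataFrame(exposure_rows),
        truth_participants=pd.DataFrame(participant_rows),
    )


def _approx_dist_m(lat1: float, lon1: float, lat2: float, lon2: float, cos_lat: float) -> float:
    # equirectangular approximation; exact enough at city scale for margin checks
    dy = (lat2 - lat1) * _M_PER_DEG
    dx = (lon2 - lon1) * _M_PER_DEG * cos_lat
    return math.hypot(dx, dy)


def null_cohort(city: AreaFrame, n: int, seed: int) -> CohortData:
    """Cohort with no type-area bias: every type's places share one spatial
    distribution, so all seven exposure measures are exchangeable."""
    config = CohortConfig(
        seed=seed,
        n_participants=n,
        type_area_bias={},
        out_of_area_rate=0.0,
        colocation_probs={t: 0.5 for t in LOCATION_TYPES if t != "live_sleep"},
    )
    return generate_cohort(city, config)


def write_cohort(
    data: CohortData,
    survey_path: str | Path,
    truth_places_path: str | Path | None = None,
    truth_exposure_path: str | Path | None = None,
) -> None:
    write_table(data.survey, survey_path)
    if truth_places_path is not None:
        write_table(data.truth_places, truth_places_path)
    if truth_exposure_path is not None:
        write_table(data.truth_exposure, truth_exposure_path)
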