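"""Location-overlap tabulations: time summaries, multiplicity, pairwise overlap.

Three descriptive tables characterize how much participants' activity spaces
overlap across the six location types:

* a time summary (median/IQR weekly hours and percent-time share per type),
* a multiplicity table counting, for k = 1..6, the unique places serving
  exactly k location types, overall and within each type's column, and
* a pairwise overlap matrix counting participants whose place for one type
  also serves another type (counts are symmetric; percentages differ because
  each column uses its own type's provider count as denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geospatial import UniquePlace
from .survey_io import LOCATION_TYPES
from .timeuse import percent_time_by_type

TOTAL = "TOTAL"
_KS = tuple(range(1, 7))


@dataclass
class MultiplicityTable:
    """Counts of unique places by multiplicity k and location type.

    ``counts`` is indexed by k = 1..6 with one column per type plus TOTAL;
    ``denominators`` gives each type's provider count (TOTAL = number of
    unique places overall).
    """

    counts: pd.DataFrame
    denominators: pd.Series

    def share(self, k: int, column: str = TOTAL) -> float:
        """Fraction of the column's denominator at multiplicity k."""
        return float(self.counts.at[k, column]) / float(self.denominators[column])


@dataclass
class OverlapMatrix:
    """Pairwise type-overlap counts and percentages (diagonal undefined)."""

    counts: pd.DataFrame
    percentages: pd.DataFrame
    denominators: pd.Series


def multiplicity_table(places: Iterable[UniquePlace]) -> MultiplicityTable:
    """Tabulate unique places by how many location types each serves."""
    places = list(places)
    counts = pd.DataFrame(
        0, index=list(_KS), columns=list(LOCATION_TYPES) + [TOTAL], dtype=int
    )
    counts.index.name = "multiplicity"
    for place in places:
        k = place.multiplicity
        counts.at[k, TOTAL] += 1
        for t in place.member_types:
            counts.at[k, t] += 1
    denominators = counts.sum(axis=0)
    denominators.name = "providers"
    return MultiplicityTable(counts=counts, denominators=denominators)


def overlap_matrix(places: Iterable[UniquePlace]) -> OverlapMatrix:
    """Pairwise overlap: cell (r, c) counts participants whose place for type
    c also carries type r; the percentage divides by type c's provider count."""
    places = list(places)
    counts = pd.DataFrame(0, index=list(LOCATION_TYPES), columns=list(LOCATION_TYPES), dtype=int)
    denom = pd.Series(0, index=list(LOCATION_TYPES), dtype=int)
    for place in places:
        for c in place.member_types:
            denom[c] += 1
            for r in place.member_types:
                if r != c:
                    counts.at[r, c] += 1
    pct = pd.DataFrame(np.nan, index=counts.index, columns=counts.columns)
    for c in LOCATION_TYPES:
        if denom[c] > 0:
            pct[c] = 100.0 * counts[c] / denom[c]
    np.fill_diagonal(pct.values, np.nan)
    return OverlapMatrix(counts=counts, percentages=pct, denominators=denom)


def any_overlap_summary(table: MultiplicityTable) -> pd.Series:
    """Per type: percent of providers whose place serves >= 2 types.

    Computed as 100 * (denominator - count at k=1) / denominator; NA when a
    type has no providers.
    """
    out = {}
    for t in LOCATION_TYPES:
        denom = int(table.denominators[t])
        if denom == 0:
            out[t] = math.nan
        else:
            solo = int(table.counts.at[1, t])
            out[t] = 100.0 * (denom - solo) / denom
    series = pd.Series(out, name="pct_any_overlap")
    series.index.name = "location_type"
    return series


def _median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    # median = midpoint of central two for even n; quartiles by linear
    # interpolation (numpy's default), pinned for reproducibility
    arr = np.asarray(values, dtype=float)
    return (
        float(np.median(arr)),
        float(np.percentile(arr, 25, method="linear")),
        float(np.percentile(arr, 75, method="linear")),
    )


def time_summary(
    places_by_participant: Mapping[str, Sequence[UniquePlace]]
) -> pd.DataFrame:
    """Per-type medians and IQRs of weekly hours and percent-time share.

    Hours use each type's own reported weekly hours (not the place-level
    maximum); shares use the containing place's time fraction, so shares of
    co-located types coincide and need not sum to 100 across types.
    """
    hours_by_type: dict[str, list[float]] = {t: [] for t in LOCATION_TYPES}
    share_by_type: dict[str, list[float]] = {t: [] for t in LOCATION_TYPES}
    n_by_type: dict[str, int] = {t: 0 for t in LOCATION_TYPES}
    for places in places_by_participant.values():
        shares = percent_time_by_type(places)
        for place in places:
            for t in place.member_types:
                n_by_type[t] += 1
                h = place.member_hours.get(t)
                if h is not None:
                    hours_by_type[t].append(h)
                if t in shares:
                    share_by_type[t].append(100.0 * shares[t])
    rows = []
    for t in LOCATION_TYPES:
        hours = hours_by_type[t]
        shares = share_by_type[t]
        h_med, h_lo, h_hi = _median_iqr(hours) if hours else (math.nan,) * 3
        s_med, s_lo, s_hi = _median_iqr(shares) if shares else (math.nan,) * 3
        rows.append(
            {
                "location_type": t,
                "n_providers": n_by_type[t],
                "pct_time_median": s_med,
                "pct_time_q1": s_lo,
                "pct_time_q3": s_hi,
                "hours_week_median": h_med,
                "hours_week_q1": h_lo,
                "hours_week_q3": h_hi,
            }
        )
    return pd.DataFrame(rows)
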