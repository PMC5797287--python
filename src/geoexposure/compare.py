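"""Statistical comparison of the seven neighborhood-exposure measures.

For each indicator, the six single-location exposures and the time-weighted
exposure form seven groups of per-participant values.  A one-way ANOVA tests
for any difference among measure means; pairwise two-sample t-tests follow,
screened against a Bonferroni-adjusted significance level.  The published
convention counts ordered pairs — 7 measures give 42 comparisons and an
adjusted alpha of 0.05/42 (0.001 at three decimals); the standard unordered
convention (21 pairs) is available as an option.

Groups are treated as independent samples even though the same participant
contributes to several measures; this mirrors the original analysis and is
recorded as a note on every report.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .timeuse import MEASURES

INDEPENDENCE_NOTE = (
    "groups share participants but are treated as independent samples"
)


@dataclass(frozen=True)
class PairwiseResult:
    measure_a: str
    measure_b: str
    t: float
    p: float
    significant: bool


@dataclass
class ComparisonReport:
    """Per-indicator ANOVA plus Bonferroni-screened pairwise differences."""

    indicator_name: str
    group_ns: dict[str, int]
    F: float
    p: float
    family_alpha: float
    n_comparisons: int
    alpha_adjusted: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    note: str = INDEPENDENCE_NOTE


def bonferroni_comparisons(
    n_measures: int, family_alpha: float = 0.05, convention: str = "ordered"
) -> tuple[int, float]:
    """Number of pairwise comparisons and the Bonferroni-adjusted alpha.

    ``convention="ordered"`` counts n(n-1) ordered pairs (the published
    convention: 7 measures -> 42, alpha 0.05/42); ``"unordered"`` counts
    n(n-1)/2 distinct pairs.
    """
    if n_measures < 2:
        raise ValueError("need at least 2 measures")
    if not (0.0 < family_alpha < 1.0):
        raise ValueError("family_alpha must be in (0, 1)")
    if convention == "ordered":
        n_comparisons = n_measures * (n_measures - 1)
    elif convention == "unordered":
        n_comparisons = n_measures * (n_measures - 1) // 2
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return n_comparisons, family_alpha / n_comparisons


def _drop_small_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    kept: dict[str, np.ndarray] = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            warnings.warn(f"group {name!r} has n < 2 and was dropped", stacklevel=3)
            continue
        kept[name] = arr
    return kept


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p over k groups.

    F = (SSB / (k-1)) / (SSW / (N-k)) with the upper-tail p from the
    F(k-1, N-k) distribution.  Degenerate cases are defined explicitly: all
    values identical -> (0, 1); zero within-group variance with distinct
    group means -> (inf, 0).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a for a in arrays if a.size >= 2]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    all_values = np.concatenate(arrays)
    n_total = all_values.size
    grand = all_values.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = k - 1
    df_w = n_total - k
    if df_w <= 0:
        raise ValueError("total n must exceed the number of groups")
    # essentially-constant data: rounding noise must not masquerade as signal
    total_ss = ssb + ssw
    if total_ss <= n_total * (1e-12 * max(1.0, abs(grand))) ** 2:
        return 0.0, 1.0
    if ssw == 0.0:
        return math.inf, 0.0
    f_stat = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return float(f_stat), p


def _two_sample_t(a: np.ndarray, b: np.ndarray, method: str) -> tuple[float, float]:
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if method == "pooled":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    elif method == "welch":
        se2a, se2b = va / na, vb / nb
        se = math.sqrt(se2a + se2b)
        if se > 0:
            df = (se2a + se2b) ** 2 / (
                se2a**2 / (na - 1) + se2b**2 / (nb - 1)
            )
        else:
            df = na + nb - 2
    else:
        raise ValueError(f"unknown pairwise test method {method!r}")
    # degenerate / rounding-noise guard, mirroring oneway_anova's convention
    scale = 1e-12 * max(1.0, abs(a.mean()), abs(b.mean()))
    if se <= scale:
        if abs(diff) <= scale:
            return 0.0, 1.0
        if se == 0.0:
            return math.copysign(math.inf, diff), 0.0
    t_stat = diff / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return float(t_stat), p


def pairwise_tests(
    groups: Mapping[str, Sequence[float]],
    alpha_adjusted: float,
    method: str = "pooled",
) -> list[PairwiseResult]:
    """Two-sample t-test for every distinct pair of groups.

    Each test is flagged significant when p < ``alpha_adjusted``.  The pooled
    (equal-variance) t is the default classical ANOVA follow-up; Welch's
    unequal-variance t is available via ``method="welch"``.
    """
    kept = _drop_small_groups(groups)
    if len(kept) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    results = []
    for (name_a, a), (name_b, b) in itertools.combinations(kept.items(), 2):
        t_stat, p = _two_sample_t(a, b, method)
        results.append(
            PairwiseResult(name_a, name_b, t_stat, p, bool(p < alpha_adjusted))
        )
    return results


def compare_all(
    exposures: pd.DataFrame,
    indicators: Sequence[str] | None = None,
    family_alpha: float = 0.05,
    convention: str = "ordered",
    method: str = "pooled",
) -> list[ComparisonReport]:
    """One ComparisonReport per indicator over the 7 measure groups.

    ``exposures`` is the long table from
    :func:`geoexposure.timeuse.compute_exposures` (columns participant_id,
    measure, indicator, value).  Indicators with fewer than 2 usable groups
    are skipped with a warning.
    """
    if indicators is None:
        indicators = list(pd.unique(exposures["indicator"]))
    reports: list[ComparisonReport] = []
    for name in indicators:
        sub = exposures[exposures["indicator"] == name]
        groups = {
            m: sub.loc[sub["measure"] == m, "value"].to_numpy()
            for m in MEASURES
            if (sub["measure"] == m).any()
        }
        kept = _drop_small_groups(groups)
        if len(kept) < 2:
            warnings.warn(f"indicator {name!r} has < 2 usable groups; skipped")
            continue
        n_comp, alpha_adj = bonferroni_comparisons(
            len(MEASURES), family_alpha, convention
        )
        f_stat, p = oneway_anova(list(kept.values()))
        pairs = pairwise_tests(kept, alpha_adj, method)
        reports.append(
            ComparisonReport(
                indicator_name=name,
                group_ns={m: int(v.size) for m, v in kept.items()},
                F=f_stat,
                p=p,
                family_alpha=family_alpha,
                n_comparisons=n_comp,
                alpha_adjusted=alpha_adj,
                pairwise=pairs,
            )
        )
    return reports


def anova_frame(reports: Sequence[ComparisonReport]) -> pd.DataFrame:
    """Flatten the per-indicator ANOVA results for writing."""
    return pd.DataFrame(
        [
            {
                "indicator": r.indicator_name,
                "F": r.F,
                "p": r.p,
                "alpha_adjusted": r.alpha_adjusted,
                "n_comparisons": r.n_comparisons,
                **{f"n_{m}": r.group_ns.get(m, 0) for m in MEASURES},
            }
            for r in reports
        ]
    )


def pairwise_frame(reports: Sequence[ComparisonReport]) -> pd.DataFrame:
    """Flatten the pairwise tests for writing."""
    rows = []
    for r in reports:
        for pw in r.pairwise:
            rows.append(
                {
                    "indicator": r.indicator_name,
                    "measure_a": pw.measure_a,
                    "measure_b": pw.measure_b,
                    "t": pw.t,
                    "p": pw.p,
                    "significant": pw.significant,
                }
            )
    return pd.DataFrame(
        rows, columns=["indicator", "measure_a", "measure_b", "t", "p", "significant"]
    )
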