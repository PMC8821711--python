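"""Nonparametric test battery and acoustic-presence summaries.

Thin, contract-checked wrappers: Shapiro-Wilk for normality, rank-sum /
Kruskal-Wallis for group comparison with Dunn-Bonferroni post-hoc, and an
effort-normalised presence-probability summary for duty-cycled recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _ss

__all__ = [
    "GroupedSamples",
    "TestReport",
    "normality_check",
    "compare_groups",
    "dunn_posthoc",
    "presence_probability",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.05


@dataclass
class GroupedSamples:
    """Numeric samples with one group label each."""

    values: np.ndarray
    labels: np.ndarray
    grouping_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("values and labels must have equal length")

    def groups(self) -> dict:
        return {g: self.values[self.labels == g]
                for g in dict.fromkeys(self.labels.tolist())}


@dataclass
class TestReport:
    test: str
    statistic: float
    p_value: float
    group_medians: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value.

    Rejects constant input and samples smaller than 3 (the test is
    undefined there).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    stat, p = _ss.shapiro(x)
    return float(stat), float(p)


def dunn_posthoc(samples: GroupedSamples) -> pd.DataFrame:
    """Dunn's pairwise rank test with Bonferroni correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) (1/n_i + 1/n_j) )
    with the tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    groups = samples.groups()
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n_total = all_vals.size
    ranks = _ss.rankdata(all_vals)

    mean_ranks, sizes, i0 = {}, {}, 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = float(ranks[i0:i0 + n].mean())
        sizes[g] = n
        i0 += n

    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ga, gb = names[a], names[b]
            se = np.sqrt(var_base * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
            z = (mean_ranks[ga] - mean_ranks[gb]) / se
            p = 2.0 * _ss.norm.sf(abs(z))
            rows.append({
                "group_a": ga, "group_b": gb, "z": float(z),
                "p_value": float(p), "p_adjusted": float(min(1.0, p * m)),
            })
    return pd.DataFrame(rows)


def compare_groups(samples: GroupedSamples, posthoc: bool = False,
                   alpha: float = DEFAULT_ALPHA) -> TestReport:
    """Two groups: Wilcoxon-Mann-Whitney; more: Kruskal-Wallis.

    If the omnibus Kruskal-Wallis is significant at ``alpha`` and
    ``posthoc`` is requested, Dunn-Bonferroni pairwise contrasts are
    attached to the report.
    """
    groups = samples.groups()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    medians = {g: float(np.median(v)) for g, v in groups.items()}

    vals = list(groups.values())
    if len(vals) == 2:
        stat, p = _ss.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        report = TestReport("mann-whitney", float(stat), float(p), medians)
    else:
        stat, p = _ss.kruskal(*vals)
        report = TestReport("kruskal-wallis", float(stat), float(p), medians)
        if posthoc and p <= alpha:
            report.posthoc = dunn_posthoc(samples)
    return report


# --------------------------------------------------------------------------
# presence probability
# --------------------------------------------------------------------------

def _clip_intervals(intervals, lo, hi):
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if e2 > s2:
            out.append((s2, e2))
    return out


def _intersect(a, b):
    """Intersection of two sorted interval lists."""
    out, i, j = [], 0, 0
    a, b = sorted(a), sorted(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _merge(intervals):
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def presence_probability(
    passages: Sequence[tuple[float, float]],
    coverage: Sequence[tuple[float, float]],
    bin_hours: float = 1.0,
) -> pd.DataFrame:
    """Per hour-of-day probability of acoustic presence, effort-normalised.

    Parameters
    ----------
    passages, coverage:
        (start_s, end_s) intervals on a common clock whose origin is a local
        midnight; hour-of-day is ``(t // 3600) % 24``.  ``coverage`` is the
        recorded (effort) time — duty-cycled protocols make this a strict
        subset of wall time, and the probability is presence time divided by
        recorded time, never by wall time.

    Returns
    -------
    DataFrame with ``bin_start_h``, ``effort_s``, ``presence_s`` and
    ``probability`` (NaN where there is no effort).
    """
    if bin_hours <= 0 or 24.0 % bin_hours != 0:
        raise ValueError("bin_hours must divide 24")
    coverage = _merge([(float(s), float(e)) for s, e in coverage])
    present = _intersect(_merge([(float(s), float(e)) for s, e in passages]), coverage)

    n_bins = int(round(24.0 / bin_hours))
    effort = np.zeros(n_bins)
    presence = np.zeros(n_bins)
    bin_s = bin_hours * 3600.0

    def accumulate(intervals, acc):
        for s, e in intervals:
            t = s
            while t < e:
                nxt = min(e, (np.floor(t / bin_s) + 1) * bin_s)
                acc[int(np.floor(t / bin_s)) % n_bins] += nxt - t
                t = nxt

    accumulate(coverage, effort)
    accumulate(present, presence)

    prob = np.where(effort > 0, presence / np.maximum(effort, 1e-300), np.nan)
    return pd.DataFrame({
        "bin_start_h": np.arange(n_bins) * bin_hours,
        "effort_s": effort,
        "presence_s": presence,
        "probability": prob,
    })
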