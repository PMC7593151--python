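"""Nonparametric group comparisons and summary conventions.

Two tests are provided: the Kruskal-Wallis rank test (tie-corrected H,
chi-square reference distribution) and a two-sample test of equal
proportions whose chi-square statistic uses a continuity correction capped
at |O - E| (so tables that differ from expectation by less than half a
count yield a statistic of exactly zero). Summaries use type-7
(linear-interpolation) quantiles and median +/- mean absolute deviation
from the median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, rankdata

__all__ = [
    "GroupSample",
    "ProportionPair",
    "TestResult",
    "kruskal_wallis",
    "proportion_test",
    "median_quartiles",
    "median_mean_abs_dev",
]


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError(f"group {self.label!r} is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")


@dataclass(frozen=True)
class ProportionPair:
    k1: int
    n1: int
    k2: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("sample sizes must be >= 1")
        if not (0 <= self.k1 <= self.n1 and 0 <= self.k2 <= self.n2):
            raise ValueError("counts must satisfy 0 <= k <= n")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float


def kruskal_wallis(groups: Sequence[GroupSample]) -> TestResult:
    """Kruskal-Wallis rank test with tie correction.

    H = [12 / (N(N+1)) * sum n_j * Rbar_j^2 - 3(N+1)] / (1 - sum(t^3 - t)/(N^3 - N))
    with midranks for ties; p from chi-square with (#groups - 1) df.
    All-identical data yields statistic 0 and p 1 (degenerate, not an error).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    values = np.concatenate([np.asarray(g.values, dtype=float) for g in groups])
    n = len(values)
    if n < 3:
        raise ValueError("need at least three observations in total")
    ranks = rankdata(values)
    h = 0.0
    start = 0
    for g in groups:
        nj = len(g.values)
        rj = ranks[start : start + nj].sum()
        h += rj * rj / nj
        start += nj
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n**3 - n)
    df = len(groups) - 1
    if denom == 0.0:  # all observations identical
        return TestResult(0.0, df, 1.0)
    h /= denom
    h = max(0.0, h)  # guard tiny negative round-off
    return TestResult(float(h), df, float(chi2.sf(h, df)))


def proportion_test(pair: ProportionPair) -> TestResult:
    """Two-sample equal-proportions chi-square with capped continuity correction.

    The 2x2 table (successes/failures per sample) is tested against equal
    proportions; the Yates correction is capped at |O - E| so the corrected
    statistic can never go below zero. df = 1, two-sided p.

    Raises
    ------
    ValueError
        When a table margin is zero (both samples all-success or
        all-failure), where the test is undefined.
    """
    obs = np.array(
        [
            [pair.k1, pair.n1 - pair.k1],
            [pair.k2, pair.n2 - pair.k2],
        ],
        dtype=float,
    )
    col = obs.sum(axis=0)
    if col[0] == 0 or col[1] == 0:
        raise ValueError("degenerate 2x2 table: a column margin is zero")
    row = obs.sum(axis=1)
    total = obs.sum()
    expected = np.outer(row, col) / total
    # in a 2x2 table |O - E| is the same for every cell
    dev = abs(obs[0, 0] - expected[0, 0])
    correction = min(0.5, dev)
    stat = float((((np.abs(obs - expected) - correction) ** 2) / expected).sum())
    return TestResult(stat, 1, float(chi2.sf(stat, 1)))


def median_quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, 25% quantile, 75% quantile) with linear interpolation (type 7)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    q25, med, q75 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q25), float(q75)


def median_mean_abs_dev(values: Sequence[float]) -> tuple[float, float]:
    """(median, mean absolute deviation from the median)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    med = float(np.median(arr))
    return med, float(np.mean(np.abs(arr - med)))
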