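"""Group statistics and cell-counting conventions.

Results are expressed as mean +/- SEM; group comparisons use two-tailed
Student's t-tests (pooled-variance by default, Welch available) and paired
comparisons a one-sample t-test on the differences, with alpha 0.05.  No
multiple-testing correction is applied.  Stereological cell counts use a 1:4
section series multiplied by 4 and dorsal/ventral fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "GroupSummary",
    "CellCountReport",
    "TTestResult",
    "mean_sem",
    "ttest_unpaired",
    "ttest_paired",
    "cell_count_report",
]


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sem: float | None  # None for n = 1
    n: int
    label: str | None = None

    def __str__(self) -> str:
        if self.sem is None:
            return f"{self.mean:g} (n = 1)"
        return f"{self.mean:g} ± {self.sem:g} (n = {self.n})"


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def mean_sem(values: Sequence[float], label: str | None = None) -> GroupSummary:
    """Mean and standard error of the mean (sample SD / sqrt(n))."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sem = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size >= 2 else None
    return GroupSummary(mean=float(x.mean()), sem=sem, n=int(x.size), label=label)


def ttest_unpaired(
    a: Sequence[float],
    b: Sequence[float],
    two_tailed: bool = True,
    welch: bool = False,
) -> TTestResult:
    """Two-sample Student's t-test (pooled variance unless ``welch``).

    Degenerate case: both samples constant with equal means gives t = 0,
    p = 1 by convention.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return TTestResult(t=0.0, df=x.size + y.size - 2, p=1.0)
    res = _st.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    p = float(res.pvalue) if two_tailed else float(res.pvalue) / 2.0
    return TTestResult(t=float(res.statistic), df=df, p=p)


def ttest_paired(
    before: Sequence[float],
    after: Sequence[float],
    two_tailed: bool = True,
) -> TTestResult:
    """Paired t-test: one-sample t on the differences.

    Conventions: all differences zero gives p = 1; constant nonzero
    differences give t = +/-inf, p = 0.
    """
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = y - x
    df = x.size - 1
    if np.all(d == 0):
        return TTestResult(t=0.0, df=df, p=1.0)
    if d.std(ddof=1) == 0:
        return TTestResult(t=math.copysign(math.inf, d.mean()), df=df, p=0.0)
    res = _st.ttest_rel(y, x)
    p = float(res.pvalue) if two_tailed else float(res.pvalue) / 2.0
    return TTestResult(t=float(res.statistic), df=df, p=p)


@dataclass(frozen=True)
class CellCountReport:
    raw_counts: tuple[int, ...]
    series_fraction: float
    estimated_total: int
    dorsal_count: int
    ventral_count: int
    dorsal_fraction_pct: float | None  # None when no cells were counted


def cell_count_report(
    section_counts: Sequence[int],
    dorsal_count: int = 0,
    ventral_count: int = 0,
    series_every: int = 4,
) -> CellCountReport:
    """Stereological estimate: bilateral counts in a 1:4 series, times 4."""
    counts = tuple(int(c) for c in section_counts)
    if any(c < 0 for c in counts) or dorsal_count < 0 or ventral_count < 0:
        raise ValueError("counts must be non-negative")
    total = series_every * sum(counts)
    dv = dorsal_count + ventral_count
    frac = 100.0 * dorsal_count / dv if dv > 0 else None
    return CellCountReport(
        raw_counts=counts,
        series_fraction=1.0 / series_every,
        estimated_total=total,
        dorsal_count=dorsal_count,
        ventral_count=ventral_count,
        dorsal_fraction_pct=frac,
    )
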