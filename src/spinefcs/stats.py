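"""Statistical comparison layer: Student t-tests and mean +/- SEM summaries.

The tests are written out from the closed-form t statistics (and verified
against scipy in the test suite): paired two-tailed t for the before/after
FCS parameters, and a pooled-variance unpaired two-tailed t applied point
by point along FRAP recovery curves, with no multiple-testing correction
by default (a Bonferroni option is exposed).  Welch's variant of the
unpaired test is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "paired_ttest",
    "unpaired_ttest",
    "unpaired_ttest_pointwise",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sem: float
    degenerate: bool = False  # singleton group: SEM undefined, reported as 0


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: float
    paired: bool
    degenerate: bool = False  # zero-variance input


def summarize(values: Sequence[float]) -> GroupSummary:
    """Mean and standard error of the mean (sample SD / sqrt(n))."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if x.size == 1:
        return GroupSummary(n=1, mean=float(x[0]), sem=0.0, degenerate=True)
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size))
    return GroupSummary(n=int(x.size), mean=float(x.mean()), sem=sem)


def _two_tailed_p(t: float, df: float) -> float:
    return float(2.0 * sps.t.sf(abs(t), df))


def paired_ttest(before: Sequence[float], after: Sequence[float]) -> TestResult:
    """Classical paired two-tailed Student t-test on aligned pairs."""
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("before and after must be equal-length 1-d samples")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    sd = np.std(d, ddof=1)
    df = n - 1
    if sd == 0:
        if d.mean() == 0:
            return TestResult(0.0, 1.0, df, paired=True, degenerate=True)
        t = np.inf if d.mean() > 0 else -np.inf
        return TestResult(t, 0.0, df, paired=True, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    return TestResult(t, _two_tailed_p(t, df), df, paired=True)


def unpaired_ttest(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> TestResult:
    """Unpaired two-tailed t-test (pooled-variance Student by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    diff = a.mean() - b.mean()
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            df = na + nb - 2
            return TestResult(
                0.0 if diff == 0 else np.copysign(np.inf, diff),
                1.0 if diff == 0 else 0.0,
                df,
                paired=False,
                degenerate=True,
            )
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = float(diff / np.sqrt(se2))
    else:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0:
            return TestResult(
                0.0 if diff == 0 else np.copysign(np.inf, diff),
                1.0 if diff == 0 else 0.0,
                df,
                paired=False,
                degenerate=True,
            )
        t = float(diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))
    return TestResult(t, _two_tailed_p(t, df), float(df), paired=False)


def unpaired_ttest_pointwise(
    group_a,
    group_b,
    welch: bool = False,
    bonferroni: bool = False,
) -> List[TestResult]:
    """Unpaired two-tailed t-test at each time point of two curve cohorts.

    ``group_a`` and ``group_b`` are (n_curves, n_timepoints) arrays sharing
    a common time grid.  No multiple-testing correction is applied unless
    ``bonferroni`` is set, in which case p-values are multiplied by the
    number of time points (capped at 1).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share a common time grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 curves per group")
    results = []
    m = a.shape[1]
    for j in range(m):
        r = unpaired_ttest(a[:, j], b[:, j], welch=welch)
        if bonferroni and not r.degenerate:
            r = TestResult(
                r.statistic, min(1.0, r.p * m), r.df, r.paired, r.degenerate
            )
        results.append(r)
    return results
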