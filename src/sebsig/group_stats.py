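"""Group summaries and the two-tailed unpaired Student's t test.

All cohort comparisons use the pooled-variance Student's t (equal-variance
assumption), which is the test that reproduces the published p-values from
the per-sample metrics; Welch's correction is available behind a flag.
Both entry points accept either raw values or an (n, mean, sd) summary, so
a comparison can be run against a group for which only summary statistics
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan, sqrt

import numpy as np
from scipy import stats as _sps


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and sample standard deviation (n-1 denominator)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n >= 2 and not self.sd >= 0:
            raise ValueError("sd must be non-negative")

    def __str__(self) -> str:
        return f"{self.mean:.1f} ± {self.sd:.1f} (n={self.n})"


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: float
    p_two_tailed: float
    zero_variance: bool = False

    def __str__(self) -> str:
        return f"t={self.t_statistic:.3f}, df={self.df:g}, p={self.p_two_tailed:.4g}"


def summarize(values) -> GroupSummary:
    """Arithmetic mean and n-1 standard deviation of a group.

    A single value yields sd = nan; an empty group is an error.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else nan
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()), sd=sd)


def _as_summary(group) -> GroupSummary:
    return group if isinstance(group, GroupSummary) else summarize(group)


def students_t_test(group_a, group_b, welch: bool = False) -> TTestResult:
    """Two-tailed unpaired t test from raw values or summaries.

    Pooled-variance Student's t by default (df = n1 + n2 - 2); Welch's
    unequal-variance form with Satterthwaite df when ``welch=True``. Two
    constant groups with equal means give t = 0, p = 1; zero pooled
    variance with unequal means gives p = 0 and sets ``zero_variance``.
    """
    a, b = _as_summary(group_a), _as_summary(group_b)
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs n >= 2")
    diff = a.mean - b.mean
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = sqrt(va + vb)
        if se == 0.0:
            return _degenerate(diff)
        df = (va + vb) ** 2 / (
            va**2 / (a.n - 1) + vb**2 / (b.n - 1)
        )
    else:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        df = a.n + b.n - 2
        if se == 0.0:
            return _degenerate(diff)
    t = diff / se
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return TTestResult(t_statistic=float(t), df=float(df), p_two_tailed=p)


def _degenerate(diff: float) -> TTestResult:
    if diff == 0.0:
        return TTestResult(0.0, 0.0, 1.0, zero_variance=True)
    return TTestResult(float(np.sign(diff)) * float("inf"), 0.0, 0.0, zero_variance=True)
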