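"""Summary statistics and the hypothesis tests used in the analysis.

Conventions: sample (n-1) standard deviations; Welch's two-sided t-test with
Satterthwaite degrees of freedom (unequal variances are the norm between
buffering conditions); classic one-way ANOVA; Bonferroni adjustment for
families of pairwise t-tests.  Report rounding is half-up, matching how the
threshold table (e.g. mean 10.6, SD 0.4 from 11.0/10.2/10.7) is printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError, ValidationError

__all__ = [
    "Summary",
    "TestResult",
    "round_half_up",
    "summarize",
    "welch_t",
    "one_way_anova",
    "bonferroni",
]


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (so 0.25 -> 0.3 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Summary:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class TestResult:
    """statistic / degrees of freedom / p-value triple, as reported."""

    statistic: float
    df: object  # float (t) or (df1, df2) (F)
    p_value: float
    kind: str
    adjusted_p: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p_value must lie in [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value:
            raise ValidationError("adjusted p cannot be below the raw p")


def summarize(values: Sequence[float], decimals: Optional[int] = None) -> Summary:
    """Arithmetic mean and sample SD (n-1), optionally half-up rounded."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("summarize needs at least one value")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
    if decimals is not None:
        mean = round_half_up(mean, decimals)
        if np.isfinite(sd):
            sd = round_half_up(sd, decimals)
    return Summary(mean=mean, sd=sd, n=int(v.size))


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / x.size + vy / y.size
    if se2 <= 0:
        raise ValidationError("zero variance in both samples: t is undefined")
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_value=float(min(p, 1.0)), kind="welch_t")


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classic one-way fixed-effects ANOVA: F = MSB/MSW on (k-1, N-k) df."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValidationError("every group needs n >= 2")
    all_v = np.concatenate(gs)
    grand = all_v.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1 = len(gs) - 1
    df2 = all_v.size - len(gs)
    if ssw == 0:
        if ssb == 0:
            raise ValidationError("no variance at all: F is undefined")
        return TestResult(statistic=float("inf"), df=(df1, df2), p_value=0.0, kind="anova")
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult(statistic=float(f), df=(df1, df2), p_value=p, kind="anova")


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list:
    """Bonferroni adjustment: min(1, m*p), order preserved."""
    p = list(map(float, p_values))
    if any(pi < 0.0 or pi > 1.0 for pi in p):
        raise DomainError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValidationError("m must be at least the number of tests")
    return [min(1.0, m * pi) for pi in p]
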