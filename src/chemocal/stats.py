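"""Method-comparison statistics.

Two-sample pooled t-test and variance-ratio F-test computed from printed
group summaries (mean, SD, n), one-way ANOVA both from raw recovery vectors
and from printed sums of squares, and the matching critical values.  All
tests are two-tailed at alpha = 0.05 by default.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaTable",
    "t_test_from_summary",
    "f_ratio_test",
    "anova_from_summary",
    "anova_oneway",
    "t_critical",
    "f_critical",
]


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Summary row for one method/analyte: mean recovery %, SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def variance(self) -> float:
        return self.sd**2

    @classmethod
    def from_observations(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=x.size)


def t_critical(alpha: float, df: int) -> float:
    """Two-tailed Student t critical value."""
    return float(sps.t.ppf(1 - alpha / 2, df))


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-tail F critical value."""
    return float(sps.f.ppf(1 - alpha, df1, df2))


def t_test_from_summary(
    a: GroupSummary, b: GroupSummary, alpha: float = 0.05, *, welch: bool = False
) -> tuple[float, float, float, float]:
    """Two-sample t-test from summaries: returns (t, df, p, t_crit).

    Pooled (equal-variance) by default, matching its use alongside the
    F-ratio variance check; ``welch=True`` switches to the unequal-variance
    form.  t is reported as a magnitude; p is two-tailed.
    """
    if welch:
        se2 = a.variance / a.n + b.variance / b.n
        t = abs(a.mean - b.mean) / np.sqrt(se2)
        df = se2**2 / (
            (a.variance / a.n) ** 2 / (a.n - 1) + (b.variance / b.n) ** 2 / (b.n - 1)
        )
    else:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.variance + (b.n - 1) * b.variance) / df
        t = abs(a.mean - b.mean) / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    p = float(2 * sps.t.sf(t, df))
    return float(t), float(df), p, t_critical(alpha, df)


def f_ratio_test(
    a: GroupSummary, b: GroupSummary, alpha: float = 0.05
) -> tuple[float, tuple[int, int], float, float]:
    """Variance-ratio test: F = larger variance / smaller variance.

    Returns (F, (df_num, df_den), two-tailed p, upper-tail f_crit).
    """
    va, vb = a.variance, b.variance
    if va >= vb:
        num, den = a, b
    else:
        num, den = b, a
    if den.variance == 0:
        raise ZeroDivisionError("zero variance in the F-ratio denominator")
    F = num.variance / den.variance
    df = (num.n - 1, den.n - 1)
    p = float(2 * min(sps.f.sf(F, *df), sps.f.cdf(F, *df)))
    return float(F), df, min(p, 1.0), f_critical(alpha, *df)


@dataclasses.dataclass(frozen=True)
class AnovaTable:
    ss_between: float
    df_between: int
    ms_between: float
    ss_within: float
    df_within: int
    ms_within: float
    f_value: float
    p_value: float
    f_crit: float


def anova_from_summary(
    ss_between: float,
    df_between: int,
    ss_within: float,
    df_within: int,
    alpha: float = 0.05,
) -> AnovaTable:
    """One-way ANOVA table from printed sums of squares and df."""
    if df_between < 1 or df_within < 1:
        raise ValueError("degrees of freedom must be positive")
    if ss_between < 0 or ss_within < 0:
        raise ValueError("sums of squares must be non-negative")
    ms_b = ss_between / df_between
    ms_w = ss_within / df_within
    if ms_w == 0:
        # no within-group variation: degenerate by convention
        f = 0.0
        p = 1.0
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_between, df_within))
    return AnovaTable(
        ss_between=ss_between,
        df_between=df_between,
        ms_between=ms_b,
        ss_within=ss_within,
        df_within=df_within,
        ms_within=ms_w,
        f_value=f,
        p_value=p,
        f_crit=f_critical(alpha, df_between, df_within),
    )


def anova_oneway(groups, alpha: float = 0.05) -> AnovaTable:
    """One-way ANOVA from raw observation vectors (e.g. recovery %)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    return anova_from_summary(
        ss_between=float(ss_between),
        df_between=len(groups) - 1,
        ss_within=ss_within,
        df_within=all_x.size - len(groups),
        alpha=alpha,
    )
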