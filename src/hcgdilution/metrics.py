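"""TAT quality indicators and the supporting statistical toolkit.

Everything a laboratory quality report needs around the in-laboratory
turnaround time (minutes from specimen reception to report dispatch):
descriptive percentile summaries, threshold-compliance counts, one- and
two-sample t-tests, Kolmogorov–Smirnov (Lilliefors) normality, Cohen's d,
and an a-priori sample-size calculation for the two-sample t-test based on
the noncentral t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "TatSummary",
    "ComplianceReport",
    "TTestResult",
    "PowerSpec",
    "summarize_tat",
    "compliance",
    "two_sample_ttest",
    "one_sample_ttest",
    "ks_normality",
    "cohens_d",
    "two_sample_power",
    "required_sample_size",
    "tat_savings",
]


@dataclass(frozen=True)
class TatSummary:
    """Percentile summary of a TAT sample (minutes).

    Percentiles use linear interpolation between closest ranks."""

    n: int
    mean: float
    median: float
    min: float
    max: float
    p5: float
    p25: float
    p75: float
    p95: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n", "mean", "median", "min", "max", "p5", "p25", "p75", "p95")}


@dataclass(frozen=True)
class ComplianceReport:
    """Fraction of TATs at or below an expectation threshold."""

    threshold: float
    n_compliant: int
    n_total: int
    rate: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("threshold", "n_compliant", "n_total", "rate")}


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float
    f_variance_ratio: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("t", "df", "p", "mean_diff", "ci_low", "ci_high", "f_variance_ratio")}


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power analysis inputs for a two-sided two-sample t-test."""

    d: float
    alpha: float = 0.05
    power: float = 0.80
    allocation: float = 1.0  # n2 = allocation * n1

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("effect size d must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.allocation <= 0:
            raise ValueError("allocation ratio must be > 0")


def summarize_tat(values: Sequence[float]) -> TatSummary:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summarize_tat needs a non-empty sample")
    if (v <= 0).any():
        raise ValueError("TAT values must be > 0")
    p5, p25, p50, p75, p95 = np.percentile(v, [5, 25, 50, 75, 95])
    return TatSummary(
        n=int(v.size), mean=float(v.mean()), median=float(p50),
        min=float(v.min()), max=float(v.max()),
        p5=float(p5), p25=float(p25), p75=float(p75), p95=float(p95),
    )


def compliance(values: Sequence[float], threshold: float) -> ComplianceReport:
    """Count TATs meeting the expectation (``value <= threshold``, inclusive)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("compliance needs a non-empty sample")
    n_ok = int((v <= threshold).sum())
    return ComplianceReport(float(threshold), n_ok, int(v.size), n_ok / v.size)


def _variance_ratio(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    lo, hi = min(va, vb), max(va, vb)
    return float(hi / lo) if lo > 0 else math.inf


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], variant: str = "student"
) -> TTestResult:
    """Independent two-sample t-test, two-sided.

    ``variant="student"`` pools variances (the conventional laboratory
    report); ``variant="welch"`` drops the equal-variance assumption.
    ``f_variance_ratio`` (larger/smaller sample variance) is always given so
    readers can judge the pooling assumption.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    ci = res.confidence_interval(0.95)
    return TTestResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        mean_diff=float(a.mean() - b.mean()),
        ci_low=float(ci.low), ci_high=float(ci.high),
        f_variance_ratio=_variance_ratio(a, b),
    )


def one_sample_ttest(values: Sequence[float], mu: float) -> TTestResult:
    """Two-sided one-sample t-test against ``mu``.

    A constant sample equal to ``mu`` is the 0/0 degenerate case and is
    defined as t = 0, p = 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("one_sample_ttest needs n >= 2")
    sd = v.std(ddof=1)
    df = v.size - 1
    if sd == 0:
        if v[0] == mu:
            return TTestResult(0.0, float(df), 1.0, 0.0, 0.0, 0.0, math.nan)
        raise ValueError("zero-variance sample differing from mu has undefined t")
    res = stats.ttest_1samp(v, mu)
    ci = res.confidence_interval(0.95)
    return TTestResult(
        t=float(res.statistic), df=float(df), p=float(res.pvalue),
        mean_diff=float(v.mean() - mu),
        ci_low=float(ci.low - mu), ci_high=float(ci.high - mu),
        f_variance_ratio=math.nan,
    )


def ks_normality(values: Sequence[float]) -> dict:
    """Kolmogorov–Smirnov normality test with estimated mean/SD (Lilliefors).

    Returns ``{"statistic", "p"}``.  The parameters are estimated from the
    sample, so Lilliefors' corrected null distribution is used rather than
    the plain K-S tables."""
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("ks_normality needs n >= 5")
    stat, p = lilliefors(v, dist="norm")
    return {"statistic": float(stat), "p": float(p)}


def cohens_d(mean1: float, mean2: float, sd: float) -> float:
    """Standardized mean difference |mean1 - mean2| / sd."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return abs(mean1 - mean2) / sd


def two_sample_power(n1: int, spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t-test at per-group sizes
    ``(n1, allocation*n1)`` via the noncentral t distribution."""
    n2 = int(math.ceil(spec.allocation * n1))
    if n1 < 2 or n2 < 2:
        return 0.0
    df = n1 + n2 - 2
    ncp = spec.d * math.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    power = float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    if math.isnan(power):  # nct underflows far in the saturated regime
        power = float(stats.norm.sf(tcrit - ncp) + stats.norm.cdf(-tcrit - ncp))
    return power


def required_sample_size(spec: PowerSpec) -> int:
    """Smallest per-group n reaching the requested power (noncentral t).

    At d = 0.50, two-sided alpha = 0.05 and power 0.80 this gives the
    familiar 64 per group."""
    # normal-approximation start, then exact integer search
    z = stats.norm.ppf(1 - spec.alpha / 2) + stats.norm.ppf(spec.power)
    n = max(2, int(math.floor(2 * (z / spec.d) ** 2)) - 2)
    while two_sample_power(n, spec) < spec.power:
        n += 1
        if n > 10_000_000:  # pragma: no cover
            raise ValueError("requested power unreachable")
    while n > 2 and two_sample_power(n - 1, spec) >= spec.power:
        n -= 1
    return n


def tat_savings(mean_before: float, mean_after: float,
                monthly_volume: float) -> dict:
    """Per-specimen and monthly TAT savings.

    ``minutes_per_specimen = mean_before - mean_after``;
    ``hours_per_month = monthly_volume * minutes_per_specimen / 60``.
    """
    minutes = mean_before - mean_after
    return {
        "minutes_per_specimen": minutes,
        "hours_per_month": monthly_volume * minutes / 60.0,
    }
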