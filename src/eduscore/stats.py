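"""Paired arm comparison with normality-driven test selection.

Each evaluation metric yields one value per document; the paired design
(one AI and one clinician document per patient profile) is compared via
the within-profile differences d = x_ai - x_clin.  Under AUTO policy the
Shapiro-Wilk test on d at alpha = .05 chooses between the paired t test
(non-rejection; reported as mean/SD) and the Wilcoxon signed-rank test
(rejection; reported as median/IQR).  The Wilcoxon test drops zero
differences, uses midranks for ties, and computes an exact two-sided
p-value by rank-sum convolution up to 12 effective pairs, switching to
the tie-corrected normal approximation beyond that.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "Summary",
    "TestKind",
    "TestPolicy",
    "TestResult",
    "summarize",
    "paired_t_test",
    "wilcoxon_signed_rank",
    "compare_paired",
    "format_p",
    "EXACT_WILCOXON_MAX_N",
]

EXACT_WILCOXON_MAX_N = 12
DEFAULT_ALPHA = 0.05


class TestKind(str, Enum):
    PAIRED_T = "PAIRED_T"
    WILCOXON = "WILCOXON"


class TestPolicy(str, Enum):
    AUTO = "AUTO"
    FORCE_T = "FORCE_T"
    FORCE_WILCOXON = "FORCE_WILCOXON"


class Summary(NamedTuple):
    """Study-style summary: mean/SD and median with quartiles."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class PairedSample:
    """Per-profile metric pairs for one metric across the two arms."""

    metric: str
    profile_ids: tuple
    x_ai: tuple
    x_clin: tuple

    def __post_init__(self) -> None:
        if not len(self.profile_ids) == len(self.x_ai) == len(self.x_clin):
            raise ValueError("profile_ids, x_ai, x_clin must align")
        if any(v is None or not np.isfinite(v) for v in (*self.x_ai, *self.x_clin)):
            raise ValueError(f"metric {self.metric!r}: missing value within a pair")

    @property
    def n(self) -> int:
        return len(self.profile_ids)

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.x_ai, dtype=float) - np.asarray(self.x_clin, dtype=float)


@dataclass(frozen=True)
class TestResult:
    metric: str
    test: TestKind
    statistic: float
    p_value: float
    n: int
    n_effective: int
    summary_ai: Summary
    summary_clin: Summary
    style: str  # "mean_sd" or "median_iqr"
    normality_p: Optional[float] = None

    def significant(self, alpha: float = DEFAULT_ALPHA) -> bool:
        return self.p_value < alpha


def summarize(values: Sequence[float]) -> Summary:
    """Mean, sample SD (n-1), median and linearly interpolated quartiles.

    The SD of a single value is undefined and reported as NaN.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return Summary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def _base_result(sample: PairedSample, kind: TestKind, stat: float, p: float,
                 n_eff: int, style: str, normality_p: Optional[float] = None) -> TestResult:
    return TestResult(
        metric=sample.metric,
        test=kind,
        statistic=float(stat),
        p_value=float(min(1.0, max(0.0, p))),
        n=sample.n,
        n_effective=n_eff,
        summary_ai=summarize(sample.x_ai),
        summary_clin=summarize(sample.x_clin),
        style=style,
        normality_p=normality_p,
    )


def paired_t_test(sample: PairedSample, normality_p: Optional[float] = None) -> TestResult:
    """Two-sided paired t test on the differences.

    t = mean(d) / (sd(d)/sqrt(n)) with df = n - 1; the p-value comes from
    the t distribution directly.
    """
    d = sample.differences
    n = d.size
    if n < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError(
            "differences have zero variance; the paired t statistic is "
            "undefined (consider the Wilcoxon test or report descriptively)"
        )
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return _base_result(sample, TestKind.PAIRED_T, t, p, n, "mean_sd", normality_p)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by convolution.

    Works on doubled ranks so midranks stay integral; enumerates the
    distribution of W+ over all 2^n equiprobable sign assignments.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    counts /= 2.0 ** len(doubled)
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(sample: PairedSample, normality_p: Optional[float] = None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on the differences.

    Zero differences are dropped (classic procedure); |d| is ranked with
    midranks for ties; W+ (sum of ranks of positive differences) is the
    statistic.  Exact enumeration when at most ``EXACT_WILCOXON_MAX_N``
    nonzero pairs remain, tie-corrected normal approximation otherwise.
    """
    d = sample.differences
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; Wilcoxon test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mean_w = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        z = (w_plus - mean_w) / math.sqrt(var_w)
        p = 2.0 * sps.norm.sf(abs(z))
    return _base_result(
        sample, TestKind.WILCOXON, w_plus, p, n, "median_iqr", normality_p
    )


def compare_paired(
    sample: PairedSample,
    policy: TestPolicy = TestPolicy.AUTO,
    alpha: float = DEFAULT_ALPHA,
) -> TestResult:
    """Select and run the paired test for one metric.

    AUTO applies Shapiro-Wilk to the differences at ``alpha``; normal
    differences go to the paired t test (reported mean/SD), non-normal to
    Wilcoxon (reported median/IQR).
    """
    policy = TestPolicy(policy)
    if policy is TestPolicy.FORCE_T:
        return paired_t_test(sample)
    if policy is TestPolicy.FORCE_WILCOXON:
        return wilcoxon_signed_rank(sample)
    d = sample.differences
    if d.size < 3:
        raise ValueError("AUTO policy needs at least 3 pairs for Shapiro-Wilk")
    if np.ptp(d) == 0:
        raise ValueError(
            "differences are constant; no paired test is defined under AUTO"
        )
    normality_p = float(sps.shapiro(d).pvalue)
    if normality_p >= alpha:
        return paired_t_test(sample, normality_p=normality_p)
    return wilcoxon_signed_rank(sample, normality_p=normality_p)


def format_p(p: float) -> str:
    """Report style: three decimals, '<.001' below that."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") or ".000"
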