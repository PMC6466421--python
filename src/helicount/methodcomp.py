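"""Method-comparison statistics: Bland–Altman agreement, paired tests.

Tools for comparing absolute CD4 counts from two devices measured on the
same samples.  The sign convention is explicit: all differences are
``method_a − method_b``, with ``method_b`` the reference for percent
differences.  Sample standard deviations use the n−1 denominator
throughout; the t-test is two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "bland_altman",
    "paired_t",
    "percent_difference",
    "sd_ratio",
    "pearson_r",
    "compare_methods",
]

LOA_FACTOR = 1.96  # normal 95% limits of agreement


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-sample counts from two methods, aligned by sample."""

    method_a: tuple
    method_b: tuple
    labels: tuple | None = None

    def __init__(self, method_a, method_b, labels=None):
        a = tuple(float(x) for x in method_a)
        b = tuple(float(x) for x in method_b)
        if len(a) != len(b):
            raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
        if labels is not None and len(tuple(labels)) != len(a):
            raise ValueError("labels length must match measurements")
        object.__setattr__(self, "method_a", a)
        object.__setattr__(self, "method_b", b)
        object.__setattr__(self, "labels", tuple(labels) if labels is not None else None)

    def __len__(self) -> int:
        return len(self.method_a)

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.method_a) - np.asarray(self.method_b)


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman bias and limits, paired t-test, correlation."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    t_stat: float
    p_value: float
    pearson_r: float
    n: int


def bland_altman(pairs: PairedMeasurements) -> tuple[float, float, float, float]:
    """Bias and 95% limits of agreement of the paired differences.

    Returns ``(bias, loa_low, loa_high, sd_diff)`` where bias is the mean
    difference and the limits are bias ± 1.96 × SD of the differences.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for dispersion statistics")
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - LOA_FACTOR * sd, bias + LOA_FACTOR * sd, sd


def paired_t(pairs: PairedMeasurements) -> tuple[float, float]:
    """Two-sided paired t-test on the differences: ``(t, p)``.

    t = mean(d) / (SD(d)/√n) with n−1 degrees of freedom.  All-equal
    differences make the statistic undefined and raise ``ValueError``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    d = pairs.differences
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t-test degenerate")
    n = len(d)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return t, p


def percent_difference(pairs: PairedMeasurements) -> np.ndarray:
    """Per-pair percent difference, 100·(a − b)/b, with b as reference."""
    b = np.asarray(pairs.method_b)
    if np.any(b == 0):
        raise ValueError("zero reference value in method_b")
    return 100.0 * pairs.differences / b


def sd_ratio(replicates_a, replicates_b) -> float:
    """Ratio of replicate sample SDs, SD(a)/SD(b) — a reproducibility measure."""
    a = np.asarray(replicates_a, dtype=float)
    b = np.asarray(replicates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per method")
    sd_b = b.std(ddof=1)
    if sd_b == 0:
        raise ValueError("zero SD in reference replicates")
    return float(a.std(ddof=1) / sd_b)


def pearson_r(pairs: PairedMeasurements) -> float:
    """Product-moment correlation between the two methods."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    a = np.asarray(pairs.method_a)
    b = np.asarray(pairs.method_b)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def compare_methods(pairs: PairedMeasurements) -> AgreementResult:
    """Full agreement panel for one set of paired measurements."""
    bias, lo, hi, sd = bland_altman(pairs)
    t, p = paired_t(pairs)
    r = pearson_r(pairs)
    return AgreementResult(
        bias=bias, loa_low=lo, loa_high=hi, sd_diff=sd,
        t_stat=t, p_value=p, pearson_r=r, n=len(pairs),
    )
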