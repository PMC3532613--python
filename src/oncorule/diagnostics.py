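"""Confusion-matrix diagnostics with exact binomial inference.

Conventions: *positive* means recurrent within the follow-up horizon and
*predicted positive* means a high-risk call.  All interval estimates are
exact Clopper-Pearson binomial intervals; paired classifiers are
compared with the exact (binomial) McNemar test on discordant pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricEstimate",
    "DiagnosticReport",
    "confusion_metrics",
    "exact_binomial_ci",
    "mcnemar_exact",
    "compare_paired_classifiers",
    "sample_size_two_proportions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts: tp/fn over recurrent patients, tn/fp over nonrecurrent."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @staticmethod
    def from_calls(calls: Sequence[str] | np.ndarray, recurred: Sequence[bool] | np.ndarray) -> "ConfusionCounts":
        """Tabulate 'high'/'low' calls against boolean outcomes."""
        calls = np.asarray(calls)
        recurred = np.asarray(recurred, dtype=bool)
        if calls.shape != recurred.shape:
            raise ValueError("calls and outcomes must align")
        high = calls == "high"
        return ConfusionCounts(
            tp=int(np.sum(high & recurred)),
            fp=int(np.sum(high & ~recurred)),
            tn=int(np.sum(~high & ~recurred)),
            fn=int(np.sum(~high & recurred)),
        )


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact 95% (by default) confidence interval."""

    estimate: float
    lower: float
    upper: float
    k: int
    n: int

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """Half-up rounding for display, as in printed reports."""
        def r(x: float) -> float:
            q = 10 ** ndigits
            return math.floor(x * q + 0.5) / q
        return r(self.estimate), r(self.lower), r(self.upper)


@dataclass(frozen=True)
class DiagnosticReport:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate | None
    npv: MetricEstimate | None
    counts: ConfusionCounts


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact CI for a binomial proportion.

    Computed from beta quantiles; the lower bound is exactly 0 when
    ``k == 0`` and the upper bound exactly 1 when ``k == n``.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def _metric(k: int, n: int, level: float) -> MetricEstimate | None:
    if n == 0:
        return None
    lo, hi = exact_binomial_ci(k, n, level)
    return MetricEstimate(estimate=k / n, lower=lo, upper=hi, k=k, n=n)


def confusion_metrics(counts: ConfusionCounts, level: float = 0.95) -> DiagnosticReport:
    """Sensitivity, specificity, PPV and NPV with exact CIs.

    PPV (resp. NPV) is reported as ``None`` when no patient was called
    high (resp. low) risk; the remaining metrics are still computed.
    """
    if counts.n_positive == 0 or counts.n_negative == 0:
        raise ValueError("need at least one recurrent and one nonrecurrent patient")
    return DiagnosticReport(
        sensitivity=_metric(counts.tp, counts.n_positive, level),
        specificity=_metric(counts.tn, counts.n_negative, level),
        ppv=_metric(counts.tp, counts.tp + counts.fp, level),
        npv=_metric(counts.tn, counts.tn + counts.fn, level),
        counts=counts,
    )


def mcnemar_exact(b: int, c: int) -> float:
    """Two-sided exact McNemar p value from discordant-pair counts.

    Under the null the smaller discordant count is Binomial(b+c, 1/2);
    the two-sided p value doubles the smaller tail, capped at 1.
    Symmetric in (b, c).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    n = b + c
    if n == 0:
        raise ValueError("no discordant pairs: McNemar test undefined")
    k = min(b, c)
    tail = float(stats.binom.cdf(k, n, 0.5))
    return min(1.0, 2.0 * tail)


@dataclass(frozen=True)
class PairedComparison:
    """Paired sensitivity/specificity comparison of two classifiers."""

    sens_a: float
    sens_b: float
    sens_discordant: tuple[int, int]
    sens_p: float | None
    spec_a: float
    spec_b: float
    spec_discordant: tuple[int, int]
    spec_p: float | None


def compare_paired_classifiers(
    calls_a: Mapping[str, str],
    calls_b: Mapping[str, str],
    outcomes: Mapping[str, bool],
) -> PairedComparison:
    """Compare two classifiers on the same patients.

    Among patients who recurred, compares the proportions called high
    risk (sensitivity) with an exact McNemar test on the discordant
    pairs; among patients who did not recur, compares the proportions
    called low risk (specificity) likewise.  A p value of ``None``
    means there were no discordant pairs for that comparison.
    """
    ids = sorted(set(calls_a) & set(calls_b) & set(outcomes))
    if not ids:
        raise ValueError("no patients shared by both classifiers and outcomes")
    a_high = np.array([calls_a[i] == "high" for i in ids])
    b_high = np.array([calls_b[i] == "high" for i in ids])
    rec = np.array([bool(outcomes[i]) for i in ids])

    def _side(mask: np.ndarray, positive_call: bool) -> tuple[float, float, tuple[int, int], float | None]:
        a = a_high[mask] == positive_call
        b = b_high[mask] == positive_call
        n = int(mask.sum())
        if n == 0:
            raise ValueError("one outcome group is empty")
        d10 = int(np.sum(a & ~b))
        d01 = int(np.sum(~a & b))
        p = mcnemar_exact(d10, d01) if d10 + d01 > 0 else None
        return float(a.mean()), float(b.mean()), (d10, d01), p

    sens_a, sens_b, sens_d, sens_p = _side(rec, True)
    spec_a, spec_b, spec_d, spec_p = _side(~rec, False)
    return PairedComparison(
        sens_a=sens_a, sens_b=sens_b, sens_discordant=sens_d, sens_p=sens_p,
        spec_a=spec_a, spec_b=spec_b, spec_discordant=spec_d, spec_p=spec_p,
    )


def sample_size_two_proportions(
    p1: float, p2: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Per-group n for a two-sided two-proportion z-test.

    Uses the unpooled normal approximation::

        n = ceil( (z_{1-alpha/2} + z_{power})^2 (p1 q1 + p2 q2) / (p1 - p2)^2 )
    """
    for p in (p1, p2):
        if not (0.0 < p < 1.0):
            raise ValueError("proportions must lie strictly in (0, 1)")
    if p1 == p2:
        raise ValueError("proportions must differ")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    num = (z_a + z_b) ** 2 * (p1 * (1 - p1) + p2 * (1 - p2))
    return math.ceil(num / (p1 - p2) ** 2)
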