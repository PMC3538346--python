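"""Luria-Delbruck fluctuation analysis by the Drake median method.

A fluctuation experiment grows many parallel cultures from small inocula and
counts revertant (mutant) colonies per culture. Because mutations arise at
random times during growth, counts are heavy-tailed ("jackpots"), and the
median is the robust summary. The Drake median estimator maps the median
count r to the expected number of mutations per culture m through

    r/m - ln(m) = 1.24,

and the mutation rate is mu = m / N_t, with N_t the cells at risk per culture
at plating. The 95% CI is nonparametric: order-statistic ranks for the median
of n counts, l = floor((n - 1.96 sqrt(n))/2) and u = ceil((1 + n +
1.96 sqrt(n))/2) (1-based), each transformed through the same m(r)/N_t map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import optimize

DRAKE_CONSTANT = 1.24


class RateError(ValueError):
    """Rate estimate undefined (zero median, too few cultures...)."""


@dataclass(frozen=True)
class FluctuationExperiment:
    """Mutant colony counts per culture plus cells at risk at plating."""

    culture_counts: tuple[int, ...]
    cells_at_risk: float

    def __post_init__(self) -> None:
        if len(self.culture_counts) < 2:
            raise ValueError("need at least 2 cultures")
        if any(c < 0 or c != int(c) for c in self.culture_counts):
            raise ValueError("culture counts must be non-negative integers")
        if self.cells_at_risk <= 0:
            raise ValueError("cells_at_risk must be positive")

    @property
    def n_cultures(self) -> int:
        return len(self.culture_counts)


@dataclass(frozen=True)
class MutationRateEstimate:
    rate: float  # mutations per cell per generation
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ValueError("CI must bracket the rate")


def median_count(counts: Sequence[float]) -> float:
    """Middle order statistic (mean of the central pair for even n)."""
    if not counts:
        raise RateError("empty count list")
    s = sorted(counts)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def drake_m(r_median: float, rtol: float = 1e-9) -> float:
    """Solve r/m - ln(m) = 1.24 for the expected mutations per culture m.

    The left side is strictly decreasing in m for r > 0, so the root is
    unique; it is bracketed and found to relative tolerance ``rtol``.
    """
    if r_median <= 0:
        raise RateError(
            "Drake median formula undefined for median <= 0 "
            "(rate only reportable as an upper bound)"
        )
    f = lambda m: r_median / m - math.log(m) - DRAKE_CONSTANT
    lo, hi = 1e-12, max(2.0 * r_median, 1.0)
    while f(hi) > 0:
        hi *= 2.0
    return float(optimize.brentq(f, lo, hi, rtol=rtol))


def median_ci_ranks(n: int, z: float = 1.96) -> tuple[int, int]:
    """1-based order-statistic ranks of a ~95% CI for the median of n values.

    Normal approximation to the binomial(n, 1/2) ranks:
    l = floor((n - z sqrt(n))/2), u = ceil((1 + n + z sqrt(n))/2), clamped to
    [1, n]. For n = 15 this gives (3, 12).
    """
    half = z * math.sqrt(n)
    low = math.floor((n - half) / 2.0)
    high = math.ceil((1.0 + n + half) / 2.0)
    if low < 1 or high > n:
        raise RateError(f"too few cultures (n={n}) for a median CI")
    return low, high


def mutation_rate(exp: FluctuationExperiment) -> MutationRateEstimate:
    """Median-based mutation rate with nonparametric 95% CI.

    rate = m(median)/N_t; CI bounds are the rank order statistics passed
    through the same transform (a zero-count bound maps to 0).
    """
    med = median_count(exp.culture_counts)
    rate = drake_m(med) / exp.cells_at_risk
    low, high = rate_ci(exp)
    return MutationRateEstimate(rate=rate, ci_low=low, ci_high=high)


def rate_ci(exp: FluctuationExperiment) -> tuple[float, float]:
    """Nonparametric 95% CI for the median-based rate."""
    if exp.n_cultures < 6:
        raise RateError("need at least 6 cultures for a median CI")
    lo_rank, hi_rank = median_ci_ranks(exp.n_cultures)
    s = sorted(exp.culture_counts)
    r_lo, r_hi = s[lo_rank - 1], s[hi_rank - 1]
    low = 0.0 if r_lo <= 0 else drake_m(r_lo) / exp.cells_at_risk
    high = 0.0 if r_hi <= 0 else drake_m(r_hi) / exp.cells_at_risk
    return low, high


def relative_rate(test: float, reference: float) -> float:
    """Fold change of a mutation rate over a reference (wild-type) rate."""
    if reference <= 0:
        raise RateError("reference rate must be positive")
    return test / reference
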