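"""Tetrad and single-spore statistics for linkage mapping.

For two linked markers a four-spore tetrad falls into one of three classes:
parental ditype (PD, both parental two-marker combinations twice), tetratype
(TT, all four combinations once) and nonparental ditype (NPD, both recombinant
combinations twice). Their proportions estimate genetic distance through the
Perkins formula

    cM = 100 * (TT/2 + 3*NPD) / (PD + TT + NPD),

which corrects for double crossovers via the NPD class. Single-spore data
estimate distance as 100 * recombinants / total spores. This module also
provides aberrant-segregation (gene-conversion) tallies, spore-viability
profiles, the meiosis-I nondisjunction bias score, chi-square comparisons and
the viability-versus-distance regression.

Tetrads that deviate from 2:2 segregation at a flanking marker, or have a
missing call there, are UNSCORABLE for that interval's tetrad tally (but still
count in segregation tallies, and their cleanly scored viable spores still
count in single-spore tallies) — this is why per-interval scored tetrads can
fall short of the number of complete tetrads, and why single-spore totals can
exceed four times the tetrad totals.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .tetrads import (
    ALLELE_M,
    ALLELE_P,
    UNSCORED,
    IntervalCounts,
    MarkerMap,
    SegregationTally,
    Tetrad,
)


class TetradClass(enum.Enum):
    PD = "PD"
    TT = "TT"
    NPD = "NPD"
    UNSCORABLE = "UNSCORABLE"


class EstimateError(ValueError):
    """Estimate undefined (no scored data, or degenerate input)."""


@dataclass(frozen=True)
class MapDistanceEstimate:
    """Point estimate with delta-method SE and normal 95% CI, in cM."""

    cm: float
    se: float
    ci_low: float
    ci_high: float
    method: str  # "perkins_tetrad" | "single_spore"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.cm <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class ViabilityProfile:
    """Distribution of viable spores per tetrad (classes 0..4).

    ``counts`` are observed tetrad tallies for empirical profiles, or class
    probabilities for model-predicted profiles; all derived quantities only
    use their ratios.
    """

    counts: tuple[float, float, float, float, float]  # index k = weight of k-viable class

    @property
    def n_tetrads(self) -> float:
        return sum(self.counts)

    @property
    def fractions(self) -> tuple[float, ...]:
        n = self.n_tetrads
        if n == 0:
            raise EstimateError("empty viability profile")
        return tuple(c / n for c in self.counts)

    @property
    def percent_viable(self) -> float:
        n = self.n_tetrads
        if n == 0:
            raise EstimateError("empty viability profile")
        return 100.0 * sum(k * c for k, c in enumerate(self.counts)) / (4 * n)


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


# ---------------------------------------------------------------------------
# classification and tallies


def classify_interval(tetrad: Tetrad, interval: tuple[str, str]) -> TetradClass:
    """Classify one four-spore-viable tetrad for one marker interval.

    UNSCORABLE when any spore lacks a call at either marker or when either
    marker deviates from 2:2 segregation (e.g. a gene-conversion tetrad).
    """
    a, b = interval
    pairs = []
    for sp in tetrad.spores:
        if a not in sp.alleles or b not in sp.alleles:
            raise KeyError(f"interval marker missing from genotype: {interval}")
        pairs.append((sp.alleles[a], sp.alleles[b]))
    if any(UNSCORED in p for p in pairs):
        return TetradClass.UNSCORABLE
    for idx in (0, 1):
        if sum(p[idx] == ALLELE_P for p in pairs) != 2:
            return TetradClass.UNSCORABLE
    n_rec = sum(p[0] != p[1] for p in pairs)
    if n_rec == 0:
        return TetradClass.PD
    if n_rec == 4:
        return TetradClass.NPD
    # 2:2 at both markers forces n_rec in {0, 2, 4}; n_rec == 2 is a tetratype
    return TetradClass.TT


def tally_intervals(
    tetrads: Iterable[Tetrad], marker_map: MarkerMap
) -> dict[tuple[str, str], IntervalCounts]:
    """Tally tetrad classes and single-spore parental/recombinant counts.

    Tetrad tallies use only four-spore-viable tetrads with a scorable class.
    Single-spore tallies use every viable spore scored at both flanking
    markers, including spores from incomplete tetrads and from tetrads that
    are UNSCORABLE as tetrads.
    """
    counts = {iv: IntervalCounts(interval=iv) for iv in marker_map.intervals}
    for tet in tetrads:
        for iv, c in counts.items():
            a, b = iv
            if tet.n_viable == 4:
                cls = classify_interval(tet, iv)
                if cls is TetradClass.PD:
                    c.PD += 1
                elif cls is TetradClass.TT:
                    c.TT += 1
                elif cls is TetradClass.NPD:
                    c.NPD += 1
            for sp in tet.spores:
                if not sp.viable:
                    continue
                va, vb = sp.alleles.get(a, UNSCORED), sp.alleles.get(b, UNSCORED)
                if UNSCORED in (va, vb):
                    continue
                if va == vb:
                    c.parental_spores += 1
                else:
                    c.recombinant_spores += 1
    return counts


# ---------------------------------------------------------------------------
# map distances


def perkins_cm(c: IntervalCounts) -> float:
    """Perkins map distance, cM, from PD/TT/NPD tallies."""
    n = c.tetrads_scored
    if n == 0:
        raise EstimateError(f"no scored tetrads for interval {c.interval}")
    return 100.0 * (c.TT / 2.0 + 3.0 * c.NPD) / n


def perkins_se_ci(c: IntervalCounts) -> MapDistanceEstimate:
    """Perkins estimate with multinomial delta-method SE and normal 95% CI.

    With f_T = TT/n and f_N = NPD/n, the variance of (T/2 + 3N)/n under
    multinomial sampling is (f_T(1-f_T)/4 + 9 f_N(1-f_N) - 3 f_T f_N)/n; the
    CI is cm +/- 1.96 se, floored at 0.
    """
    n = c.tetrads_scored
    cm = perkins_cm(c)
    f_t, f_n = c.TT / n, c.NPD / n
    var = (0.25 * f_t * (1 - f_t) + 9.0 * f_n * (1 - f_n) - 3.0 * f_t * f_n) / n
    se = 100.0 * math.sqrt(max(var, 0.0))
    return MapDistanceEstimate(
        cm=cm,
        se=se,
        ci_low=max(0.0, cm - 1.96 * se),
        ci_high=cm + 1.96 * se,
        method="perkins_tetrad",
    )


def single_spore_cm(parental: int, recombinant: int) -> float:
    """Single-spore map distance: 100 * recombinants / total spores."""
    total = parental + recombinant
    if total == 0:
        raise EstimateError("no scored spores")
    return 100.0 * recombinant / total


def single_spore_se_ci(parental: int, recombinant: int) -> MapDistanceEstimate:
    """Single-spore estimate with binomial SE and normal 95% CI."""
    total = parental + recombinant
    cm = single_spore_cm(parental, recombinant)
    f = recombinant / total
    se = 100.0 * math.sqrt(f * (1 - f) / total)
    return MapDistanceEstimate(
        cm=cm,
        se=se,
        ci_low=max(0.0, cm - 1.96 * se),
        ci_high=cm + 1.96 * se,
        method="single_spore",
    )


def cumulative_distance(
    estimates: Sequence[MapDistanceEstimate],
) -> MapDistanceEstimate:
    """Sum per-interval estimates; SEs combine in quadrature."""
    if not estimates:
        raise EstimateError("no estimates to accumulate")
    methods = {e.method for e in estimates}
    if len(methods) > 1:
        raise ValueError(f"mixed estimate methods: {sorted(methods)}")
    cm = sum(e.cm for e in estimates)
    se = math.sqrt(sum(e.se**2 for e in estimates))
    return MapDistanceEstimate(
        cm=cm,
        se=se,
        ci_low=max(0.0, cm - 1.96 * se),
        ci_high=cm + 1.96 * se,
        method=methods.pop(),
    )


def fold_decrease(reference: float, test: float) -> float:
    """Ratio reference/test (e.g. wild-type cM over mutant cM)."""
    if test <= 0:
        raise EstimateError("fold decrease undefined for non-positive test distance")
    return reference / test


# ---------------------------------------------------------------------------
# segregation, viability, comparisons


def segregation_tally(tetrads: Iterable[Tetrad], marker: str) -> SegregationTally:
    """Tally 2:2 vs 3:1/1:3 segregation of one marker.

    Only four-spore-viable tetrads with all four spores scored at the marker
    are classified (ratios are P:M counts).
    """
    n22 = n31 = n13 = 0
    seen = False
    for tet in tetrads:
        alleles = []
        for sp in tet.spores:
            if marker not in sp.alleles:
                raise KeyError(f"marker {marker!r} absent from tetrad {tet.tetrad_id}")
            alleles.append(sp.alleles[marker])
        seen = True
        if tet.n_viable != 4 or UNSCORED in alleles:
            continue
        n_p = sum(a == ALLELE_P for a in alleles)
        if n_p == 2:
            n22 += 1
        elif n_p == 3:
            n31 += 1
        elif n_p == 1:
            n13 += 1
        # 4:0 / 0:4 tetrads are neither 2:2 nor singly aberrant; excluded
    return SegregationTally(
        marker=marker, normal_2_2=n22, aberrant_3_1=n31, aberrant_1_3=n13
    )


def viability_profile(tetrads: Iterable[Tetrad]) -> ViabilityProfile:
    counts = [0, 0, 0, 0, 0]
    for tet in tetrads:
        counts[tet.n_viable] += 1
    return ViabilityProfile(counts=tuple(counts))


def profile_from_counts(counts: Mapping[int, float]) -> ViabilityProfile:
    """Build a profile from a {k viable -> count or probability} mapping."""
    return ViabilityProfile(counts=tuple(float(counts.get(k, 0)) for k in range(5)))


def ndj_bias_score(profile: ViabilityProfile) -> float:
    """Meiosis-I nondisjunction signature: (f4 + f2 + f0) - (f3 + f1).

    One MI nondisjunction kills an even number of spores (the two nullisomic
    ones), enriching the even viable-spore classes; random spore death fills
    the odd classes. Higher is a stronger 4-2-0 signature.
    """
    f = profile.fractions
    return (f[4] + f[2] + f[0]) - (f[3] + f[1])


def chi_square_2xk(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2 x k table.

    Returns (statistic, upper-tail p) with k-1 degrees of freedom.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ValueError(f"expected a 2 x k table with k >= 2, got shape {arr.shape}")
    if (arr.sum(axis=0) <= 0).any() or (arr.sum(axis=1) <= 0).any():
        raise EstimateError("degenerate table: zero marginal")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def fit_viability_vs_distance(
    points: Sequence[tuple[float, float]],
) -> RegressionFit:
    """OLS of spore viability (%) on map distance (cM); R^2 = squared
    sample correlation."""
    if len(points) < 2:
        raise EstimateError("need at least 2 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise EstimateError("degenerate fit: constant map distance")
    if np.ptp(y) == 0:
        raise EstimateError("degenerate fit: constant viability")
    fit = sps.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


# ---------------------------------------------------------------------------
# no-interference theory (closed forms used as oracles and for documentation)


def expected_class_probs(m: float) -> tuple[float, float, float]:
    """Exact (PD, TT, NPD) probabilities for Poisson(m) crossovers per
    bivalent with no chromatid interference.

    TT(m) = (2/3)(1 - exp(-3m/2)); PD - NPD = exp(-m); classes sum to 1.
    """
    if m < 0:
        raise ValueError("mean crossover count must be >= 0")
    tt = (2.0 / 3.0) * (1.0 - math.exp(-1.5 * m))
    npd = 0.5 * (1.0 - math.exp(-m) - tt)
    pd = 1.0 - tt - npd
    return pd, tt, npd


def expected_perkins_cm(d_cm: float) -> float:
    """Expectation of the Perkins estimate when the true distance is d_cm
    under the Poisson no-interference model (m = d/50).

    Close to d below ~20 cM and attenuated above (e.g. 32.2 at d = 35)."""
    _, tt, npd = expected_class_probs(d_cm / 50.0)
    return 100.0 * (tt / 2.0 + 3.0 * npd)
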