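"""Obligate-crossover / achiasmate-disjunction spore-viability model.

Every homolog pair needs at least one crossover (the obligate crossover) to
direct its meiosis-I disjunction. When crossover formation is reduced
fold-wise, the expected crossovers per chromosome drop to wt_mean/fold, and
under a Poisson crossover-count model the chance a pair is achiasmate (E0,
zero crossovers) is exp(-mean). An achiasmate pair either still disjoins
correctly (probability ``p_disjoin``, e.g. by a distributive or
centromere-pairing backup mechanism) or nondisjoins at meiosis I: both
homologs travel to one pole, making the two spores from the other pole
nullisomic (dead) and the two from the first pole disomic (viable by default
— yeast disomes germinate). Meiosis II and sister segregation are assumed
faithful; an independent per-spore background death is applied last.

The resulting distribution of viable spores per tetrad is computed exactly by
enumerating spore survival masks chromosome by chromosome; an MI
nondisjunction kills an even number of spores, which is what produces the
characteristic excess of 4-, 2- and 0-viable-spore tetrads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .stats import ViabilityProfile

# the six possible nullisomic spore pairs of an MI nondisjunction
SPORE_PAIRS: tuple[tuple[int, int], ...] = tuple(combinations(range(4), 2))


@dataclass(frozen=True)
class ChromosomeCrossoverSpec:
    chromosome: str
    wt_mean_crossovers: float
    fold_reduction: float

    def __post_init__(self) -> None:
        if self.wt_mean_crossovers <= 0:
            raise ValueError("wild-type mean crossovers must be positive")
        if self.fold_reduction < 1:
            raise ValueError("fold reduction must be >= 1")


@dataclass(frozen=True)
class DisjunctionModel:
    """Parameters of achiasmate-chromosome fate and background spore death."""

    p_disjoin: float = 0.9
    disomic_viable: bool = True
    background_death: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_disjoin", "background_death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def expected_crossovers(spec: ChromosomeCrossoverSpec) -> float:
    """Mean crossovers per meiosis after fold-reduction: wt_mean/fold."""
    return spec.wt_mean_crossovers / spec.fold_reduction


def prob_achiasmate(mean: float) -> float:
    """P(zero crossovers) = exp(-mean) under Poisson crossover counts."""
    if mean < 0:
        raise ValueError("mean crossover count must be >= 0")
    return math.exp(-mean)


def crossover_screen(
    specs: Sequence[ChromosomeCrossoverSpec],
) -> dict[str, dict[str, float]]:
    """Per-chromosome reduced means and achiasmate probabilities."""
    out = {}
    for spec in specs:
        mean = expected_crossovers(spec)
        out[spec.chromosome] = {
            "mean_crossovers": mean,
            "p_achiasmate": prob_achiasmate(mean),
            "at_least_one_expected": mean >= 1.0,
        }
    return out


def viability_distribution(
    e0_probs: Sequence[float], model: DisjunctionModel
) -> ViabilityProfile:
    """Exact distribution of viable spores per tetrad.

    Each chromosome independently is chiasmate (prob 1 - e0), achiasmate but
    correctly disjoined (e0 * p_disjoin) — both harmless — or nondisjoined
    (e0 * (1 - p_disjoin)), which kills a uniformly chosen spore pair
    (nullisomic) and, if disomes are inviable, the complementary pair too.
    Background death is applied independently to each surviving spore.
    Exact for any modest number of chromosomes (16 spore-survival states).
    """
    for e0 in e0_probs:
        if not 0.0 <= e0 <= 1.0:
            raise ValueError(f"achiasmate probability out of range: {e0}")

    # distribution over 4-bit survival masks, bit k = spore k alive
    masks = {0b1111: 1.0}
    for e0 in e0_probs:
        q = e0 * (1.0 - model.p_disjoin)
        if q == 0.0:
            continue
        new: dict[int, float] = {}
        for mask, p in masks.items():
            new[mask] = new.get(mask, 0.0) + p * (1.0 - q)
            for pair in SPORE_PAIRS:
                killed = (1 << pair[0]) | (1 << pair[1])
                if not model.disomic_viable:
                    killed = 0b1111
                new_mask = mask & ~killed
                new[new_mask] = new.get(new_mask, 0.0) + p * q / len(SPORE_PAIRS)
        masks = new

    # fold in background death: alive spores survive independently w.p. 1-bg
    bg = model.background_death
    probs = [0.0] * 5
    for mask, p in masks.items():
        alive = bin(mask).count("1")
        for k in range(alive + 1):
            binom = math.comb(alive, k) * (1 - bg) ** k * bg ** (alive - k)
            probs[k] += p * binom
    return ViabilityProfile(counts=tuple(probs))
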