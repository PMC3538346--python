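"""Chromatid-level synthetic meiosis and fluctuation-culture generator.

No raw dissection data are deposited for this study, so downstream statistics
are exercised against synthetic tetrads drawn from an explicit generative
model:

* each bivalent carries four chromatids (two sisters per homolog); per
  interval the crossover count is Poisson with mean m = d/50, where d is the
  interval's true distance in cM — one obligatory crossover per meiosis makes
  every tetrad a tetratype, i.e. 50 cM;
* each crossover picks one chromatid of each homolog uniformly (no chromatid
  interference) and exchanges the distal segments; crossover positions are
  not interfering either (Poisson counts);
* crossing over is split across pathway classes — interference-dependent,
  interference-independent, and a small residual — that share placement rules
  and differ only in rate multipliers, so genotype presets (wild type and the
  crossover-pathway knockouts) are just per-class scalings of the wild-type
  distances;
* gene conversion is marker-local: each marker x tetrad converts with a fixed
  probability, overwriting one random spore's allele (3:1 or 1:3);
* chromosomes with zero crossovers (achiasmate) risk meiosis-I
  nondisjunction per the obligate-crossover viability model, killing spore
  pairs; a background per-spore death applies on top;
* fluctuation cultures grow by synchronous doubling with per-division
  mutation, giving the characteristic heavy-tailed (jackpot) mutant counts.

Everything is reproducible: a mandatory seed drives a single
``numpy.random.Generator`` and identical configs give byte-identical output
files and manifests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .fluctuation import FluctuationExperiment
from .fixtures import load_fixture
from .stats import perkins_cm, tally_intervals
from .tetrads import (
    ALLELE_M,
    ALLELE_P,
    UNSCORED,
    MarkerMap,
    SporeGenotype,
    Tetrad,
    write_marker_maps,
    write_tetrad_table,
)
from .viability_model import SPORE_PAIRS, DisjunctionModel

# wild-type pathway composition of crossing over: interference-dependent,
# interference-independent, residual (see docs/methods.md)
PATHWAY_SHARES = (0.45, 0.45, 0.10)

# genome-wide wild-type mean crossovers per chromosome per meiosis
WT_TOTAL_CROSSOVERS = {"III": 3.0, "VII": 8.0, "VIII": 4.0, "XV": 7.0}

CM_PER_CROSSOVER_MEAN = 50.0  # d cM <-> Poisson mean d/50 per bivalent


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one genotype's synthetic dissection data."""

    maps: dict[str, MarkerMap]
    interval_cm: dict[str, tuple[float, ...]]  # chromosome -> per-interval wild-type cM
    pathway_scaling: tuple[float, float] = (1.0, 1.0)  # (interference, non-interference)
    conversion_rate: float = 0.0
    disjunction: DisjunctionModel = field(default_factory=DisjunctionModel)
    n_tetrads: int = 2000
    seed: int = 0
    genotype: str = "custom"
    wt_total_crossovers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be >= 1")
        if not 0.0 <= self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate must be in [0, 1]")
        if any(s < 0 for s in self.pathway_scaling):
            raise ValueError("pathway scalings must be >= 0")
        for chrom, mm in self.maps.items():
            dists = self.interval_cm.get(chrom)
            if dists is None or len(dists) != len(mm.intervals):
                raise ValueError(
                    f"chromosome {chrom}: need one distance per interval "
                    f"({len(mm.intervals)})"
                )
            if any(d < 0 for d in dists):
                raise ValueError("interval distances must be >= 0")

    @property
    def rate_factor(self) -> float:
        """Effective crossover-rate multiplier relative to wild type."""
        s_int, s_non = self.pathway_scaling
        w_int, w_non, w_res = PATHWAY_SHARES
        return w_int * s_int + w_non * s_non + w_res

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["maps"] = {
            c: [[m, p] for m, p in mm.markers] for c, mm in self.maps.items()
        }
        d["interval_cm"] = {c: list(v) for c, v in self.interval_cm.items()}
        return d


@dataclass
class Manifest:
    """Realized-event record of one simulation; reproducible from (config, seed).

    ``achiasmate_flags`` (one {chromosome: bool} per meiosis, true when the
    whole chromosome — mapped intervals plus unmapped remainder — received
    zero crossovers) feed :func:`apply_viability`; the JSON serialization
    keeps only their per-chromosome totals.
    """

    config: dict
    crossovers_per_interval: dict[str, list[int]]
    achiasmate_per_chromosome: dict[str, int]
    achiasmate_flags: list[dict[str, bool]] = field(default_factory=list, repr=False)
    n_conversions: int = 0
    n_ndj_events: int = 0
    tallies: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("achiasmate_flags")
        return json.dumps(d, indent=1, sort_keys=True)


def simulate_tetrads(
    config: SimulationConfig,
) -> tuple[list[Tetrad], Manifest]:
    """Draw tetrads from the chromatid-level crossover model.

    Returns the tetrads and a manifest carrying realized crossover counts and
    the per-meiosis achiasmate flags consumed by :func:`apply_viability`.
    """
    rng = np.random.default_rng(config.seed)
    factor = config.rate_factor
    chroms = sorted(config.maps)

    xo_tally = {c: [0] * len(config.maps[c].intervals) for c in chroms}
    achiasmate_tally = {c: 0 for c in chroms}
    flags: list[dict[str, bool]] = []
    tetrads: list[Tetrad] = []

    for i in range(config.n_tetrads):
        tid = f"{config.genotype.replace(' ', '_')}-{i + 1:05d}"
        alleles_per_spore: list[dict[str, str]] = [{} for _ in range(4)]
        meiosis_flags: dict[str, bool] = {}
        for chrom in chroms:
            mm = config.maps[chrom]
            names = mm.marker_names
            n_mark = len(names)
            # spore s follows original strand perm[s]; strands 0,1 are the
            # parent-1 chromatids, 2,3 parent-2. Each crossover joins the
            # proximal part of one original strand per homolog to the other's
            # distal part, i.e. swaps which paths the two strands carry.
            perm = [0, 1, 2, 3]
            chromatids = np.zeros((4, n_mark), dtype=np.int8)
            chromatids[:, 0] = [0, 0, 1, 1]
            total_xo = 0
            for j, d in enumerate(config.interval_cm[chrom]):
                m = d / CM_PER_CROSSOVER_MEAN * factor
                k = int(rng.poisson(m)) if m > 0 else 0
                xo_tally[chrom][j] += k
                total_xo += k
                for _ in range(k):
                    c1 = int(rng.integers(0, 2))
                    c2 = int(rng.integers(2, 4))
                    u, v = perm.index(c1), perm.index(c2)
                    perm[u], perm[v] = perm[v], perm[u]
                for s in range(4):
                    chromatids[s, j + 1] = 0 if perm[s] < 2 else 1
            # unmapped remainder of the chromosome, for achiasmate calls only
            wt_total = config.wt_total_crossovers.get(chrom, 0.0)
            mapped_mean = sum(config.interval_cm[chrom]) / CM_PER_CROSSOVER_MEAN
            rem = max(0.0, wt_total - mapped_mean) * factor
            if rem > 0:
                total_xo += int(rng.poisson(rem))
            achiasmate = total_xo == 0
            meiosis_flags[chrom] = achiasmate
            achiasmate_tally[chrom] += achiasmate
            for s in range(4):
                for j, name in enumerate(names):
                    alleles_per_spore[s][name] = (
                        ALLELE_P if chromatids[s, j] == 0 else ALLELE_M
                    )
        spores = tuple(
            SporeGenotype(
                tetrad_id=tid, spore_index=s + 1, viable=True,
                alleles=alleles_per_spore[s],
            )
            for s in range(4)
        )
        tetrads.append(Tetrad(tetrad_id=tid, spores=spores))
        flags.append(meiosis_flags)

    manifest = Manifest(
        config=config.to_jsonable(),
        crossovers_per_interval=xo_tally,
        achiasmate_per_chromosome=achiasmate_tally,
        achiasmate_flags=flags,
    )
    return tetrads, manifest


def apply_gene_conversion(
    tetrads: Sequence[Tetrad], rate: float, rng: np.random.Generator
) -> int:
    """Convert each marker x tetrad with probability ``rate``.

    A conversion overwrites one uniformly chosen spore's allele with the
    opposite allele, producing 3:1 or 1:3 segregation with equal chance on
    balanced input. Tetrads are modified in place; returns the number of
    conversion events.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    n_events = 0
    if rate == 0.0:
        return 0
    for tet in tetrads:
        markers = tet.spores[0].alleles.keys()
        for marker in markers:
            if rng.random() >= rate:
                continue
            sp = tet.spores[int(rng.integers(0, 4))]
            cur = sp.alleles[marker]
            if cur == UNSCORED:
                continue
            sp.alleles[marker] = ALLELE_M if cur == ALLELE_P else ALLELE_P
            n_events += 1
    return n_events


def apply_viability(
    tetrads: Sequence[Tetrad],
    model: DisjunctionModel,
    achiasmate_flags: Sequence[Mapping[str, bool]],
    rng: np.random.Generator,
) -> int:
    """Resolve achiasmate chromosomes and background death; mask dead spores.

    Each achiasmate chromosome nondisjoins with probability 1 - p_disjoin,
    killing a uniformly chosen spore pair (nullisomic) and, if disomes are
    inviable, the complementary pair too. Dead spores get all alleles masked
    to unscored. Returns the number of nondisjunction events.
    """
    n_ndj = 0
    for tet, flags in zip(tetrads, achiasmate_flags):
        alive = [True] * 4
        for chrom, achiasmate in sorted(flags.items()):
            if not achiasmate:
                continue
            if rng.random() < model.p_disjoin:
                continue
            n_ndj += 1
            pair = SPORE_PAIRS[int(rng.integers(0, len(SPORE_PAIRS)))]
            for s in pair:
                alive[s] = False
            if not model.disomic_viable:
                alive = [False] * 4
        for s in range(4):
            if alive[s] and rng.random() < model.background_death:
                alive[s] = False
        for s, sp in enumerate(tet.spores):
            if not alive[s]:
                sp.viable = False
                sp.alleles = {m: UNSCORED for m in sp.alleles}
    return n_ndj


def simulate_fluctuation(
    mu: float,
    n_initial: int,
    n_final: int,
    n_cultures: int,
    rng: np.random.Generator,
) -> FluctuationExperiment:
    """Grow cultures by synchronous doubling with per-division mutation.

    ``n_final`` must equal ``n_initial * 2**g`` for an integer number of
    generations g. Per generation every non-mutant divides once; each
    division yields a mutant with probability ``mu``; mutant lineages double.
    Mutant counts are the classic heavy-tailed Luria-Delbruck distribution
    with P(0 mutants) = (1 - mu)^(n_final - n_initial).
    """
    if not 0.0 <= mu < 1.0:
        raise ValueError("mu must be in [0, 1)")
    if n_initial < 1 or n_final <= n_initial:
        raise ValueError("need n_final > n_initial >= 1")
    g = round(np.log2(n_final / n_initial))
    if n_initial * 2**g != n_final:
        raise ValueError("n_final must be n_initial * 2**g for integer g")
    nonmutant = np.full(n_cultures, n_initial, dtype=np.int64)
    mutant = np.zeros(n_cultures, dtype=np.int64)
    for _ in range(g):
        new = rng.binomial(nonmutant, mu)
        mutant = 2 * mutant + new
        nonmutant = 2 * nonmutant - new
    return FluctuationExperiment(
        culture_counts=tuple(int(x) for x in mutant), cells_at_risk=float(n_final)
    )


# ---------------------------------------------------------------------------
# study presets and the end-to-end generator

# per-genotype (interference, non-interference) pathway multipliers
GENOTYPE_SCALING = {
    "wild type": (1.0, 1.0),
    "mlh3Δ": (0.0, 1.0),
    "mms4Δ": (1.0, 0.0),
    "mlh3Δ mms4Δ": (0.0, 0.0),
}

DEFAULT_CONVERSION_RATE = 0.01
DEFAULT_DISJUNCTION = DisjunctionModel(
    p_disjoin=0.9, disomic_viable=True, background_death=0.08
)

# the two strain backgrounds of the study and the chromosomes each is marked on
BACKGROUNDS = {"NHY": ("III", "VII", "VIII"), "EAY": ("XV",)}


def wild_type_interval_cm() -> dict[str, tuple[float, ...]]:
    """Wild-type per-interval distances: Perkins estimates recomputed from the
    packaged printed tetrad counts."""
    maps = load_fixture("marker_maps")
    t5, t7 = load_fixture("table5"), load_fixture("table7")
    out = {}
    for chrom, mm in maps.items():
        table = t5 if chrom == "XV" else t7
        dists = []
        for a, b in mm.intervals:
            row = table["wild type"][f"{a}-{b}"]
            dists.append(perkins_cm(row.counts))
        out[chrom] = tuple(dists)
    return out


def preset_config(
    genotype: str,
    n_tetrads: int = 2000,
    seed: int = 0,
    chromosomes: Sequence[str] | None = None,
) -> SimulationConfig:
    """Build the study-condition config for one genotype preset."""
    if genotype not in GENOTYPE_SCALING:
        raise KeyError(
            f"unknown preset {genotype!r}; available: {sorted(GENOTYPE_SCALING)}"
        )
    maps = load_fixture("marker_maps")
    interval_cm = wild_type_interval_cm()
    if chromosomes is not None:
        maps = {c: maps[c] for c in chromosomes}
        interval_cm = {c: interval_cm[c] for c in chromosomes}
    return SimulationConfig(
        maps=maps,
        interval_cm=interval_cm,
        pathway_scaling=GENOTYPE_SCALING[genotype],
        conversion_rate=DEFAULT_CONVERSION_RATE,
        disjunction=DEFAULT_DISJUNCTION,
        n_tetrads=n_tetrads,
        seed=seed,
        genotype=genotype,
        wt_total_crossovers=dict(WT_TOTAL_CROSSOVERS),
    )


def simulate_study_genotype(config: SimulationConfig) -> tuple[list[Tetrad], Manifest]:
    """Full generative chain for one genotype: crossovers, conversion, NDJ."""
    tetrads, manifest = simulate_tetrads(config)
    rng = np.random.default_rng(config.seed + 1)
    manifest.n_conversions = apply_gene_conversion(
        tetrads, config.conversion_rate, rng
    )
    manifest.n_ndj_events = apply_viability(
        tetrads, config.disjunction, manifest.achiasmate_flags, rng
    )
    manifest.tallies = {
        chrom: {
            f"{iv[0]}-{iv[1]}": {
                "PD": c.PD, "TT": c.TT, "NPD": c.NPD,
                "parental": c.parental_spores,
                "recombinant": c.recombinant_spores,
            }
            for iv, c in tally_intervals(tetrads, config.maps[chrom]).items()
        }
        for chrom in sorted(config.maps)
    }
    return tetrads, manifest


def generate_study(
    out_dir: str | Path,
    genotypes: Sequence[str] = tuple(GENOTYPE_SCALING),
    n_tetrads: int = 2000,
    seed: int = 0,
    fluctuation_cultures: int = 15,
) -> dict[str, Path]:
    """Write a complete synthetic study: per-genotype, per-background tetrad
    tables, marker maps, fluctuation counts, and a JSON manifest each.

    Chromosome XV tetrads are written separately from III/VII/VIII, matching
    the study's two strain backgrounds. Fluctuation counts are drawn at the
    genotype's published median rate (wild type 4.71e-7, null 26.5e-7
    per cell per generation, others at wild type). Returns written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    maps = load_fixture("marker_maps")
    map_path = out_dir / "marker_maps.tsv"
    write_marker_maps(maps, map_path)
    written = {"marker_maps": map_path}

    t3 = load_fixture("table3")
    mu_by_genotype = {
        "wild type": t3["MLH3"].median_rate_e7 * 1e-7,
        "mlh3Δ": t3["mlh3Δ"].median_rate_e7 * 1e-7,
    }

    for gi, genotype in enumerate(genotypes):
        slug = (
            genotype.replace(" ", "_").replace("Δ", "d")
        )
        for bi, (background, chroms) in enumerate(sorted(BACKGROUNDS.items())):
            config = preset_config(
                genotype,
                n_tetrads=n_tetrads,
                seed=seed + 1000 * gi + 100 * bi,
                chromosomes=chroms,
            )
            tetrads, manifest = simulate_study_genotype(config)
            markers = [m for c in chroms for m in maps[c].marker_names]
            tet_path = out_dir / f"tetrads_{slug}_{background}.tsv"
            write_tetrad_table(tetrads, tet_path, markers)
            man_path = out_dir / f"manifest_{slug}_{background}.json"
            man_path.write_text(manifest.to_json(), encoding="utf-8")
            written[f"tetrads/{genotype}/{background}"] = tet_path
            written[f"manifest/{genotype}/{background}"] = man_path

        mu = mu_by_genotype.get(genotype, mu_by_genotype["wild type"])
        rng = np.random.default_rng(seed + 1000 * gi + 77)
        exp = simulate_fluctuation(
            mu, n_initial=20, n_final=20 * 2**20,
            n_cultures=fluctuation_cultures, rng=rng,
        )
        fluc_path = out_dir / f"fluctuation_{slug}.tsv"
        with open(fluc_path, "w", encoding="utf-8") as fh:
            fh.write("strain\tculture\tmutant_colonies\tcells_plated\n")
            for i, count in enumerate(exp.culture_counts):
                fh.write(f"{genotype}\t{i + 1}\t{count}\t{int(exp.cells_at_risk)}\n")
        written[f"fluctuation/{genotype}"] = fluc_path
    return written
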