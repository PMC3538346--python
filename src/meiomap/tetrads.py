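"""Domain types and file I/O for yeast tetrad genotype data.

A *tetrad* is the group of four haploid spores produced by one meiosis of a
diploid, recovered intact by dissection. Each viable spore is genotyped at a
set of markers and its allele recorded relative to the two parent haploids:
``P`` (parent-1 allele), ``M`` (parent-2 allele) or ``-`` (unscored, which is
also the mandatory code for every marker of a dead spore).

The on-disk dialects are tab-separated text:

* tetrad genotype table — header ``tetrad_id  spore  viable  <marker...>``,
  one row per spore, ``spore`` in 1..4, ``viable`` in {0,1}, alleles in
  {P, M, -}; lines starting with ``#`` are comments;
* marker map — header ``chromosome  marker  position_kb``, rows ordered by
  position within each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

ALLELE_P = "P"
ALLELE_M = "M"
UNSCORED = "-"
VALID_ALLELES = frozenset({ALLELE_P, ALLELE_M, UNSCORED})


class TetradFileError(ValueError):
    """Malformed tetrad table: bad row, unknown column, or broken tetrad."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered markers along one chromosome, positions in kb.

    ``intervals`` are the adjacent marker pairs; a chromosome with k markers
    defines k-1 intervals.
    """

    chromosome: str
    markers: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValueError(f"chromosome {self.chromosome}: need >= 2 markers")
        pos = [p for _, p in self.markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(
                f"chromosome {self.chromosome}: positions must strictly increase"
            )
        names = [m for m, _ in self.markers]
        if len(set(names)) != len(names):
            raise ValueError(f"chromosome {self.chromosome}: duplicate marker names")

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.markers)

    @property
    def intervals(self) -> tuple[tuple[str, str], ...]:
        names = self.marker_names
        return tuple(zip(names, names[1:]))


@dataclass
class SporeGenotype:
    tetrad_id: str
    spore_index: int
    viable: bool
    alleles: dict[str, str]

    def __post_init__(self) -> None:
        if self.spore_index not in (1, 2, 3, 4):
            raise ValueError(f"spore index must be 1-4, got {self.spore_index}")
        bad = set(self.alleles.values()) - VALID_ALLELES
        if bad:
            raise TetradFileError(
                f"tetrad {self.tetrad_id} spore {self.spore_index}: "
                f"invalid allele code(s) {sorted(bad)}"
            )
        if not self.viable and any(a != UNSCORED for a in self.alleles.values()):
            raise ValueError(
                f"tetrad {self.tetrad_id} spore {self.spore_index}: "
                "dead spore carries scored alleles"
            )


@dataclass
class Tetrad:
    """Four spores from one meiosis; spore order carries no meaning."""

    tetrad_id: str
    spores: tuple[SporeGenotype, SporeGenotype, SporeGenotype, SporeGenotype]

    def __post_init__(self) -> None:
        if len(self.spores) != 4:
            raise TetradFileError(
                f"tetrad {self.tetrad_id}: expected 4 spores, got {len(self.spores)}"
            )
        if sorted(s.spore_index for s in self.spores) != [1, 2, 3, 4]:
            raise TetradFileError(
                f"tetrad {self.tetrad_id}: spore indices must be a permutation of 1-4"
            )

    @property
    def n_viable(self) -> int:
        return sum(s.viable for s in self.spores)


@dataclass
class IntervalCounts:
    """PD/TT/NPD tetrad tallies and parental/recombinant single-spore tallies
    for one marker interval."""

    interval: tuple[str, str]
    PD: int = 0
    TT: int = 0
    NPD: int = 0
    parental_spores: int = 0
    recombinant_spores: int = 0

    @property
    def tetrads_scored(self) -> int:
        return self.PD + self.TT + self.NPD

    @property
    def spores_total(self) -> int:
        return self.parental_spores + self.recombinant_spores

    def __post_init__(self) -> None:
        for name in ("PD", "TT", "NPD", "parental_spores", "recombinant_spores"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SegregationTally:
    """2:2 vs aberrant (3:1 / 1:3) segregation of one marker across tetrads."""

    marker: str
    normal_2_2: int
    aberrant_3_1: int
    aberrant_1_3: int

    @property
    def n_tetrads(self) -> int:
        return self.normal_2_2 + self.aberrant_3_1 + self.aberrant_1_3

    @property
    def percent_aberrant(self) -> float:
        n = self.n_tetrads
        if n == 0:
            return 0.0
        return 100.0 * (self.aberrant_3_1 + self.aberrant_1_3) / n


# ---------------------------------------------------------------------------
# file I/O


def read_marker_maps(path: str | Path) -> dict[str, MarkerMap]:
    """Read a marker-map TSV into one MarkerMap per chromosome."""
    df = pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
    required = {"chromosome", "marker", "position_kb"}
    if not required.issubset(df.columns):
        raise TetradFileError(f"marker map {path}: missing columns {required - set(df.columns)}")
    maps = {}
    for chrom, grp in df.groupby("chromosome", sort=False):
        maps[str(chrom)] = MarkerMap(
            chromosome=str(chrom),
            markers=tuple((str(r.marker), float(r.position_kb)) for r in grp.itertuples()),
        )
    return maps


def write_marker_maps(maps: Mapping[str, MarkerMap], path: str | Path) -> None:
    rows = [
        {"chromosome": mm.chromosome, "marker": name, "position_kb": pos}
        for mm in maps.values()
        for name, pos in mm.markers
    ]
    pd.DataFrame(rows, columns=["chromosome", "marker", "position_kb"]).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_tetrad_table(
    path: str | Path, markers: Sequence[str] | None = None
) -> list[Tetrad]:
    """Parse a tetrad genotype TSV into Tetrad records.

    ``markers``, when given, is the full set of legal marker columns (e.g. the
    concatenated marker names of the study's chromosomes); columns outside it
    raise a schema error. Rows are grouped by ``tetrad_id``; a group without
    exactly four spores is an integrity error.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [
            (i + 1, line.rstrip("\n"))
            for i, line in enumerate(fh)
            if line.strip() and not line.startswith("#")
        ]
    if not lines:
        raise TetradFileError(f"{path}: empty file")
    header = lines[0][1].split("\t")
    if header[:3] != ["tetrad_id", "spore", "viable"]:
        raise TetradFileError(
            f"{path}: header must start with 'tetrad_id spore viable', got {header[:3]}"
        )
    marker_cols = header[3:]
    if markers is not None:
        unknown = set(marker_cols) - set(markers)
        if unknown:
            raise TetradFileError(f"{path}: unknown marker column(s) {sorted(unknown)}")

    spores_by_tetrad: dict[str, list[SporeGenotype]] = {}
    order: list[str] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise TetradFileError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        tid, spore_s, viable_s = fields[0], fields[1], fields[2]
        try:
            spore_i = int(spore_s)
        except ValueError as exc:
            raise TetradFileError(f"{path}:{lineno}: bad spore index {spore_s!r}") from exc
        if viable_s not in ("0", "1"):
            raise TetradFileError(f"{path}:{lineno}: viable must be 0 or 1, got {viable_s!r}")
        alleles = dict(zip(marker_cols, fields[3:]))
        bad = set(alleles.values()) - VALID_ALLELES
        if bad:
            raise TetradFileError(
                f"{path}:{lineno}: invalid allele code(s) {sorted(bad)}"
            )
        sg = SporeGenotype(
            tetrad_id=tid, spore_index=spore_i, viable=viable_s == "1", alleles=alleles
        )
        if tid not in spores_by_tetrad:
            order.append(tid)
        spores_by_tetrad.setdefault(tid, []).append(sg)

    tetrads = []
    for tid in order:
        group = spores_by_tetrad[tid]
        if len(group) != 4:
            raise TetradFileError(
                f"{path}: tetrad {tid} has {len(group)} spore rows, expected 4"
            )
        tetrads.append(Tetrad(tetrad_id=tid, spores=tuple(group)))
    return tetrads


def write_tetrad_table(
    tetrads: Iterable[Tetrad], path: str | Path, markers: Sequence[str]
) -> None:
    """Write tetrads in the genotype TSV dialect (round-trips with the reader)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["tetrad_id", "spore", "viable"] + list(markers)) + "\n")
        for tet in tetrads:
            for sp in sorted(tet.spores, key=lambda s: s.spore_index):
                row = [tet.tetrad_id, str(sp.spore_index), "1" if sp.viable else "0"]
                row += [sp.alleles.get(m, UNSCORED) for m in markers]
                fh.write("\t".join(row) + "\n")
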