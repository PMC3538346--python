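"""Packaged copies of the study's printed summary tables.

The quantitative inputs of the study exist only as printed tables (no raw
dissection data are deposited), so they ship inside the package as
tab-separated text under ``meiomap/data`` and are exposed through
:func:`load_fixture`. Counts are stored exactly as printed; derived numbers
(map distances, fold changes, R^2 ...) are recomputed from them by the
statistics layer, never read back.

Fixture names: ``table3`` (fluctuation-assay mutation rates), ``table4``
(spore viability and cumulative chromosome XV distance per strain), ``table5``
(chromosome XV per-interval counts), ``table6`` (per-chromosome cumulative
distances and fold decreases), ``table7`` (chromosome III/VII/VIII
per-interval counts), ``table8`` (aberrant marker segregation) and
``marker_maps`` (marker positions in kb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .tetrads import IntervalCounts, MarkerMap, read_marker_maps

_FIXTURES = (
    "table3",
    "table4",
    "table5",
    "table6",
    "table7",
    "table8",
    "marker_maps",
)


def _data_path(name: str):
    return resources.files("meiomap").joinpath("data", f"{name}.tsv")


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, sep="\t", comment="#", encoding="utf-8")


@dataclass(frozen=True)
class IntervalRow:
    """One genotype x interval row of a per-interval count table."""

    genotype: str
    chromosome: str
    interval: str
    spores_total: int
    parental: int
    recombinant: int
    cm_single: float
    tetrads: int
    PD: int
    TT: int
    NPD: int
    ci_low: float
    ci_high: float

    @property
    def counts(self) -> IntervalCounts:
        a, b = self.interval.split("-", 1)
        return IntervalCounts(
            interval=(a, b),
            PD=self.PD,
            TT=self.TT,
            NPD=self.NPD,
            parental_spores=self.parental,
            recombinant_spores=self.recombinant,
        )


class _IntervalTable(dict):
    """genotype -> interval -> IntervalRow; interval lookup accepts either
    marker order ("URA3-LEU2" or "LEU2-URA3")."""

    def rows(self):
        for per_geno in self.values():
            yield from per_geno.values()


class _IntervalLookup(dict):
    def __missing__(self, key: str):
        a, sep, b = key.partition("-")
        flipped = f"{b}{sep}{a}"
        if flipped in self:
            return self[flipped]
        raise KeyError(key)


def _load_interval_table(name: str) -> _IntervalTable:
    df = _read(name)
    table = _IntervalTable()
    for r in df.itertuples():
        row = IntervalRow(
            genotype=r.genotype,
            chromosome=r.chromosome,
            interval=r.interval,
            spores_total=int(r.spores_total),
            parental=int(r.parental),
            recombinant=int(r.recombinant),
            cm_single=float(r.cm_single),
            tetrads=int(r.tetrads),
            PD=int(r.PD),
            TT=int(r.TT),
            NPD=int(r.NPD),
            ci_low=float(r.ci_low),
            ci_high=float(r.ci_high),
        )
        if row.parental + row.recombinant != row.spores_total:
            raise ValueError(
                f"{name} {row.genotype} {row.interval}: "
                f"parental+recombinant != spores_total"
            )
        if row.PD + row.TT + row.NPD > row.tetrads:
            raise ValueError(
                f"{name} {row.genotype} {row.interval}: PD+TT+NPD exceeds tetrads"
            )
        table.setdefault(row.genotype, _IntervalLookup())[row.interval] = row
    return table


@dataclass(frozen=True)
class MutationRateRow:
    genotype: str
    group: str
    n: int
    median_rate_e7: float
    ci_low_e7: float
    ci_high_e7: float
    relative: float
    phenotype: str


@dataclass(frozen=True)
class ViabilityRow:
    strain: str
    spore_viability_pct: float
    cm: float
    n_tetrads: int
    regression_set: bool


@dataclass(frozen=True)
class CumulativeRow:
    genotype: str
    spore_viability_pct: float | None
    n_tetrads: int | None
    cumulative: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SegregationRow:
    genotype: str
    chromosome: str
    n_tetrads: int
    percent_by_marker: dict[str, float]
    total: float


def load_fixture(name: str):
    """Return the printed numbers of one packaged table, keyed for lookup.

    Returns, by name:

    * ``table3`` — dict genotype -> :class:`MutationRateRow`
    * ``table4`` — dict strain -> :class:`ViabilityRow`
    * ``table5`` / ``table7`` — dict genotype -> dict interval -> :class:`IntervalRow`
    * ``table6`` — dict genotype -> :class:`CumulativeRow` (the key
      ``"fold decrease"`` holds the printed fold ratios in ``cumulative``)
    * ``table8`` — dict (genotype, chromosome) -> :class:`SegregationRow`
    * ``marker_maps`` — dict chromosome -> :class:`MarkerMap`
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(_FIXTURES)}")

    if name in ("table5", "table7"):
        return _load_interval_table(name)

    if name == "table3":
        df = _read(name)
        return {
            r.genotype: MutationRateRow(
                genotype=r.genotype,
                group=r.group,
                n=int(r.n),
                median_rate_e7=float(r.median_rate_e7),
                ci_low_e7=float(r.ci_low_e7),
                ci_high_e7=float(r.ci_high_e7),
                relative=float(r.relative),
                phenotype=r.phenotype,
            )
            for r in df.itertuples()
        }

    if name == "table4":
        df = _read(name)
        return {
            r.strain: ViabilityRow(
                strain=r.strain,
                spore_viability_pct=float(r.spore_viability_pct),
                cm=float(r.cM),
                n_tetrads=int(r.n_tetrads),
                regression_set=bool(r.regression_set),
            )
            for r in df.itertuples()
        }

    if name == "table6":
        df = _read(name)
        out = {}
        for r in df.itertuples():
            cumulative = {}
            for chrom in ("III", "VII", "VIII", "XV"):
                v = getattr(r, f"cm_{chrom}")
                if pd.notna(v):
                    cumulative[chrom] = float(v)
            out[r.genotype] = CumulativeRow(
                genotype=r.genotype,
                spore_viability_pct=(
                    float(r.spore_viability_pct) if pd.notna(r.spore_viability_pct) else None
                ),
                n_tetrads=int(r.n_tetrads) if pd.notna(r.n_tetrads) else None,
                cumulative=cumulative,
            )
        return out

    if name == "table8":
        df = _read(name)
        out = {}
        for (geno, chrom), grp in df.groupby(["genotype", "chromosome"], sort=False):
            markers = {
                r.marker: float(r.percent_aberrant)
                for r in grp.itertuples()
                if r.marker != "TOTAL"
            }
            total = float(grp.loc[grp.marker == "TOTAL", "percent_aberrant"].iloc[0])
            out[(geno, chrom)] = SegregationRow(
                genotype=geno,
                chromosome=chrom,
                n_tetrads=int(grp.n_tetrads.iloc[0]),
                percent_by_marker=markers,
                total=total,
            )
        return out

    with resources.as_file(_data_path("marker_maps")) as p:
        return read_marker_maps(p)
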