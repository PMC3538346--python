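"""End-to-end analysis runs: tabulate -> estimate -> compare -> report.

Two input modes mirror how the study's data exist:

* genotype level — tetrad genotype tables (one per genotype, possibly several
  files across strain backgrounds), from which everything is tallied;
* summary level — per-interval count tables in the printed-table layout
  (``genotype chromosome interval spores_total parental recombinant tetrads
  PD TT NPD``), the only form in which the original data are available.

``analyze`` produces a per-interval estimates TSV, a cumulative/fold table, a
segregation tally, viability profiles with nondisjunction-bias scores, the
viability-versus-distance regression, and chi-square viability comparisons
against a reference genotype, plus a JSON summary. All report tables carry
full precision; round for display.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import stats
from .fixtures import load_fixture
from .tetrads import MarkerMap, Tetrad, read_marker_maps, read_tetrad_table
from .simulate import generate_study

log = logging.getLogger("meiomap")


class PipelineError(ValueError):
    """Invalid run configuration or unusable input."""


@dataclass
class RunConfig:
    out_dir: Path
    marker_map_path: Path | None = None
    tetrad_tables: dict[str, list[Path]] = field(default_factory=dict)
    summary_table: Path | None = None
    reference_genotype: str | None = None
    viability_by_genotype: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def _interval_rows_from_tetrads(
    genotype: str, maps: Mapping[str, MarkerMap], tetrads: Sequence[Tetrad]
) -> list[dict]:
    rows = []
    marker_sets = {c: set(mm.marker_names) for c, mm in maps.items()}
    for chrom, mm in maps.items():
        # only tetrads genotyped on this chromosome's markers
        sub = [
            t for t in tetrads
            if marker_sets[chrom] <= set(t.spores[0].alleles.keys())
        ]
        if not sub:
            continue
        tallies = stats.tally_intervals(sub, mm)
        for iv, c in tallies.items():
            base = {
                "genotype": genotype,
                "chromosome": chrom,
                "interval": f"{iv[0]}-{iv[1]}",
                "PD": c.PD, "TT": c.TT, "NPD": c.NPD,
                "parental": c.parental_spores,
                "recombinant": c.recombinant_spores,
            }
            if c.tetrads_scored > 0:
                est = stats.perkins_se_ci(c)
                rows.append(base | {
                    "method": est.method, "cM": est.cm, "se": est.se,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                })
            if c.spores_total > 0:
                est = stats.single_spore_se_ci(
                    c.parental_spores, c.recombinant_spores
                )
                rows.append(base | {
                    "method": est.method, "cM": est.cm, "se": est.se,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                })
    return rows


def _interval_rows_from_summary(path: Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
    required = {
        "genotype", "chromosome", "interval", "spores_total",
        "parental", "recombinant", "tetrads", "PD", "TT", "NPD",
    }
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"summary table {path}: missing columns {sorted(missing)}")
    rows = []
    for r in df.itertuples():
        a, _, b = r.interval.partition("-")
        c = stats.IntervalCounts(
            interval=(a, b), PD=int(r.PD), TT=int(r.TT), NPD=int(r.NPD),
            parental_spores=int(r.parental), recombinant_spores=int(r.recombinant),
        )
        base = {
            "genotype": r.genotype, "chromosome": r.chromosome,
            "interval": r.interval, "PD": c.PD, "TT": c.TT, "NPD": c.NPD,
            "parental": c.parental_spores, "recombinant": c.recombinant_spores,
        }
        if c.tetrads_scored > 0:
            est = stats.perkins_se_ci(c)
            rows.append(base | {
                "method": est.method, "cM": est.cm, "se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
            })
        if c.spores_total > 0:
            est = stats.single_spore_se_ci(c.parental_spores, c.recombinant_spores)
            rows.append(base | {
                "method": est.method, "cM": est.cm, "se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
            })
    return rows


def _cumulative_table(interval_df: pd.DataFrame, reference: str | None) -> pd.DataFrame:
    rows = []
    for (genotype, chrom, method), grp in interval_df.groupby(
        ["genotype", "chromosome", "method"], sort=False
    ):
        ests = [
            stats.MapDistanceEstimate(
                cm=r.cM, se=r.se, ci_low=r.ci_low, ci_high=r.ci_high, method=method
            )
            for r in grp.itertuples()
        ]
        cum = stats.cumulative_distance(ests)
        rows.append({
            "genotype": genotype, "chromosome": chrom, "method": method,
            "cM": cum.cm, "se": cum.se,
        })
    cum_df = pd.DataFrame(rows)
    if reference is not None and reference in set(cum_df.genotype):
        ref = cum_df[cum_df.genotype == reference].set_index(["chromosome", "method"]).cM
        cum_df["fold_vs_reference"] = [
            (ref.get((r.chromosome, r.method), float("nan")) / r.cM) if r.cM > 0 else float("nan")
            for r in cum_df.itertuples()
        ]
    return cum_df


def analyze(run: RunConfig) -> dict[str, Path]:
    """Run the full report over the configured inputs; returns written paths."""
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    interval_rows: list[dict] = []
    summary: dict = {"genotypes": {}}
    tetrads_by_genotype: dict[str, list[Tetrad]] = {}

    if run.tetrad_tables:
        if run.marker_map_path is None:
            raise PipelineError("tetrad-table mode requires a marker map")
        maps = read_marker_maps(run.marker_map_path)
        all_markers = [m for mm in maps.values() for m in mm.marker_names]
        for genotype, paths in run.tetrad_tables.items():
            tets: list[Tetrad] = []
            for p in paths:
                tets.extend(read_tetrad_table(p, markers=all_markers))
            if not tets:
                raise PipelineError(f"genotype {genotype}: no tetrads read")
            tetrads_by_genotype[genotype] = tets
            log.info("genotype %s: %d tetrads", genotype, len(tets))
            interval_rows.extend(_interval_rows_from_tetrads(genotype, maps, tets))
    elif run.summary_table is not None:
        interval_rows = _interval_rows_from_summary(run.summary_table)
    else:
        raise PipelineError("no input: provide tetrad tables or a summary table")

    if not interval_rows:
        raise PipelineError("inputs contained no scorable intervals")

    interval_df = pd.DataFrame(interval_rows)[
        ["genotype", "chromosome", "interval", "method", "cM", "se",
         "ci_low", "ci_high", "PD", "TT", "NPD", "parental", "recombinant"]
    ]
    p = out / "intervals.tsv"
    interval_df.to_csv(p, sep="\t", index=False, encoding="utf-8")
    written["intervals"] = p

    cum_df = _cumulative_table(interval_df, run.reference_genotype)
    p = out / "cumulative.tsv"
    cum_df.to_csv(p, sep="\t", index=False, encoding="utf-8")
    written["cumulative"] = p

    if tetrads_by_genotype:
        seg_rows = []
        for genotype, tets in tetrads_by_genotype.items():
            markers = sorted({m for t in tets for m in t.spores[0].alleles})
            four_viable = [t for t in tets if t.n_viable == 4]
            for marker in markers:
                with_marker = [
                    t for t in four_viable if marker in t.spores[0].alleles
                ]
                tally = stats.segregation_tally(with_marker, marker)
                seg_rows.append({
                    "genotype": genotype, "marker": marker,
                    "normal_2_2": tally.normal_2_2,
                    "aberrant_3_1": tally.aberrant_3_1,
                    "aberrant_1_3": tally.aberrant_1_3,
                    "percent_aberrant": tally.percent_aberrant,
                })
            profile = stats.viability_profile(tets)
            summary["genotypes"][genotype] = {
                "n_tetrads": profile.n_tetrads,
                "viable_spore_counts": list(profile.counts),
                "percent_viable": profile.percent_viable,
                "ndj_bias_score": stats.ndj_bias_score(profile),
            }
        p = out / "segregation.tsv"
        pd.DataFrame(seg_rows).to_csv(p, sep="\t", index=False, encoding="utf-8")
        written["segregation"] = p

        ref = run.reference_genotype
        if ref in tetrads_by_genotype:
            ref_prof = stats.viability_profile(tetrads_by_genotype[ref])
            ref_viable = sum(k * c for k, c in enumerate(ref_prof.counts))
            ref_dead = 4 * ref_prof.n_tetrads - ref_viable
            for genotype, tets in tetrads_by_genotype.items():
                if genotype == ref:
                    continue
                prof = stats.viability_profile(tets)
                viable = sum(k * c for k, c in enumerate(prof.counts))
                dead = 4 * prof.n_tetrads - viable
                stat, pval = stats.chi_square_2xk(
                    [[ref_viable, ref_dead], [viable, dead]]
                )
                summary["genotypes"][genotype]["viability_chi2_vs_reference"] = {
                    "statistic": stat, "p_value": pval,
                }

        # viability vs cumulative tetrad distance across genotypes
        points = []
        tet_cum = cum_df[cum_df.method == "perkins_tetrad"]
        for genotype in tetrads_by_genotype:
            total = tet_cum[tet_cum.genotype == genotype].cM.sum()
            pct = summary["genotypes"][genotype]["percent_viable"]
            points.append((total, pct))
        if len(points) >= 3:
            try:
                fit = stats.fit_viability_vs_distance(points)
                summary["regression"] = {
                    "slope": fit.slope, "intercept": fit.intercept,
                    "r_squared": fit.r_squared, "points": points,
                }
            except stats.EstimateError:
                pass

    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8")
    written["summary"] = p
    return written


def simulate_study_run(
    out_dir: str | Path,
    genotypes: Sequence[str] | None = None,
    n_tetrads: int = 2000,
    seed: int = 0,
) -> dict[str, Path]:
    """Generate a synthetic study (thin wrapper over the generator)."""
    from .simulate import GENOTYPE_SCALING

    genos = tuple(genotypes) if genotypes else tuple(GENOTYPE_SCALING)
    return generate_study(out_dir, genotypes=genos, n_tetrads=n_tetrads, seed=seed)
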