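# meiomap

Tetrad analysis of meiotic crossing over in budding yeast: linkage mapping
from dissection data, spore-viability and nondisjunction statistics,
fluctuation-assay mutation rates, an obligate-crossover viability model, and
a chromatid-level synthetic meiosis generator.

## The problem

In *Saccharomyces cerevisiae*, crossovers between homologous chromosomes are
formed by two pathways — an interference-dependent one (Msh4-Msh5 /
Mlh1-Mlh3) and an interference-independent one (Mus81-Mms4) — and every
homolog pair needs at least one crossover (the obligate crossover) to
segregate correctly at meiosis I. Strains mutated in these pathways are
characterized by dissecting tetrads (the four spores of one meiosis),
genotyping the spores at chromosome-spanning markers, and asking: how far did
crossing over fall, and what did that do to spore viability and chromosome
disjunction? A parallel mismatch-repair phenotype is read out from Lys+
reversion fluctuation assays.

This package implements that entire analysis for anyone working with yeast
tetrad data: geneticists mapping intervals from dissection tables, and
modellers asking what viability patterns a given crossover deficit predicts.

## The statistics

* **Tetrad classes.** For two linked markers each tetrad is a parental
  ditype (PD), tetratype (TT) or nonparental ditype (NPD); map distance by
  the Perkins formula, `cM = 100 (TT/2 + 3 NPD)/(PD+TT+NPD)`, with a
  multinomial delta-method SE. Single-spore distance is
  `100 × recombinants / total spores`.
* **Viability.** Viable-spores-per-tetrad profiles; an MI-nondisjunction
  bias score `(f4+f2+f0) − (f3+f1)` capturing the 4-2-0 signature; χ²
  comparisons; OLS of viability on cumulative map distance.
* **Mutation rates.** Drake median method, `r/m − ln m = 1.24`,
  `rate = m/N_t`, with nonparametric order-statistic 95% CIs.
* **Obligate-crossover model.** Reduced per-chromosome crossover means
  `wt_mean/fold`; achiasmate probability `e^{−mean}` (Poisson); exact
  viable-spore distributions under achiasmate disjunction vs MI
  nondisjunction.
* **Synthetic meiosis.** Poisson crossovers (`m = d/50` per bivalent), no
  chromatid interference, marker-local gene conversion, NDJ-driven spore
  death, Luria–Delbrück cultures — with manifests, fully seeded.

The printed summary tables of the source study (counts, viabilities, rates)
ship as packaged fixtures and are the reference inputs for the analyses.

## Worked example

```python
>>> import meiomap as mm
>>> row = mm.load_fixture("table5")["wild type"]["URA3-LEU2"]
>>> (row.PD, row.TT, row.NPD)
(607, 456, 5)
>>> est = mm.perkins_se_ci(row.counts)
>>> round(est.cm, 2), round(est.se, 2)
(22.75, 0.95)
>>> round(mm.single_spore_cm(row.parental, row.recombinant), 1)
21.7
```

The wild-type URA3-LEU2 interval on chromosome XV measures 22.75 ± 0.95 cM
from 1068 complete tetrads (inside the published 95% CI, 21.8–23.8), and
21.7 cM from 4644 single spores — tetrad and single-spore estimators agree
within sampling error, as they should for a well-behaved interval.

The analysis itself is a sequence of numbered drivers:

```sh
python analysis/01_printed_tables.py     # re-derive published numbers from printed counts
python analysis/02_simulate_study.py     # generate the synthetic dissection study
python analysis/03_analyze_synthetic.py  # analyze it and check parameter recovery
python analysis/04_viability_model.py    # obligate-crossover arithmetic and predictions
python analysis/05_fluctuation.py        # mutation-rate arithmetic and calibration
```

`01` prints, among other things, the double-mutant fold decreases per
chromosome `{III: 6.1, VII: 7.2, VIII: 16.5, XV: 11.4}` and the
viability-distance fit `viability = 50.0 + 0.460 × cM, R² = 0.87`; `04`
prints the per-chromosome expected crossovers after fold reduction (only
chromosome VII keeps ≥ 1) and the predicted viability profiles across
achiasmate-disjunction efficiencies. Small tables land under `results/`;
bulk simulated data land under `scratch/` and are regenerable from the seed.

A `meiomap` CLI wraps the same library for shell use
(`meiomap analyze|simulate|fluctuation|fixtures --help`).

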