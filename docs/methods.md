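# Methods

`meiomap` reimplements the genetic-analysis toolchain of a budding-yeast
meiotic crossover study: tetrad-based linkage mapping, spore-viability and
nondisjunction statistics, fluctuation-assay mutation rates, an
obligate-crossover viability model, and a synthetic meiosis generator that
stands in for the unpublished raw dissection data. This note records the
models, the defaults and why, and what the synthetic data can and cannot
show.

## Tetrad classification and map distances

For a pair of linked markers, a four-spore-viable tetrad is classified by the
multiset of its two-marker allele pairs: parental ditype (PD), tetratype
(TT), nonparental ditype (NPD). A tetrad is UNSCORABLE for an interval when
any spore lacks a call at a flanking marker or when a flanking marker
deviates from 2:2 segregation (a gene-conversion tetrad). Unscorable tetrads
still feed the per-marker segregation tallies, and their cleanly genotyped
viable spores still feed single-spore tallies. Two consequences, both
visible in the published count tables, drive two design choices:

* the tetrad map-distance denominator is the number of *scored* tetrads
  (PD+TT+NPD), not the number of complete tetrads — the published
  confidence intervals are only consistent with the scored-tetrad
  denominator on rows where several tetrads were unscorable;
* single-spore totals may exceed four times the tetrad totals, because
  spores from incomplete and unscorable tetrads still count.

Distances:

* Perkins (tetrad): `cM = 100 (TT/2 + 3 NPD) / (PD+TT+NPD)`, which corrects
  for double crossovers through the NPD class.
* Single spore: `cM = 100 × recombinants / total spores`.

The study delegated standard errors to an external web tool whose estimator
is not published. Here the Perkins SE is the multinomial delta method:
with `f_T = TT/n`, `f_N = NPD/n`,

    se = 100 sqrt( (f_T(1-f_T)/4 + 9 f_N(1-f_N) - 3 f_T f_N) / n ),

with a normal 95% interval floored at zero. This matches a parametric
bootstrap of the multinomial to three digits (tested), but it is not
guaranteed to equal the published intervals; accordingly, agreement with the
published tables is asserted on point estimates (containment in the printed
CIs), never on CI equality. Cumulative distances are sums of per-interval
point estimates with SEs combined in quadrature; published cumulative values
differ from plain Perkins sums by up to ~0.6 cM (the external tool's
estimator differs slightly), so cross-genotype fold decreases are computed
from printed cumulative values when reproducing the published ratios.

Validity range: the Perkins estimator is nearly unbiased below ~20 cM under
the no-interference model used throughout (exact expectation available in
closed form, `expected_perkins_cm`); at 35 cM its expectation is already
attenuated to 32.2 cM. Estimates above ~35 cM are outside the validated
range and the tests treat them as such.

## Aberrant segregation, viability profiles, NDJ bias

Gene conversion appears as 3:1 or 1:3 marker segregation among
four-spore-viable tetrads; `percent_aberrant = 100 (n31 + n13) / n`. (4:0
and 0:4 patterns are excluded from both numerator and the 2:2 class; they do
not occur under the single-event conversion model.)

The viability profile is the distribution of viable spores per tetrad
(classes 0–4). Meiosis-I nondisjunction kills spores in pairs (the two
nullisomic spores of a tetrad), enriching even classes; the bias score
`(f4 + f2 + f0) − (f3 + f1)` quantifies the characteristic 4-2-0 signature.
Random (binomial) spore death yields lower scores than any NDJ-containing
mixture matched for overall viability (property-tested on a grid of
disjunction efficiencies).

Viability comparisons between genotypes use Pearson chi-square on
viable/dead spore counts without continuity correction, df = k−1 for a 2×k
table. The viability-versus-distance relationship is ordinary least squares
of spore viability (%) on cumulative map distance (cM) with R² the squared
sample correlation; over the ten published strain pairs this reproduces
R² = 0.87.

## Fluctuation assays (Drake median method)

Mutation rates from Lys+ reversion counts use the median estimator: the
median mutant count r maps to expected mutations per culture m via
`r/m − ln m = 1.24` (unique root, bracketed bisection to 1e−9 relative
tolerance), and `rate = m / N_t` with N_t the cells at risk per culture.
The 95% CI is nonparametric: order-statistic ranks for the median of n
counts, `l = floor((n − 1.96√n)/2)`, `u = ceil((1 + n + 1.96√n)/2)`
(1-based; (3, 12) at n = 15), each bound passed through the same transform;
a zero-count bound maps to rate 0. The rank formula is the normal
approximation to binomial(n, ½); it is validated by coverage simulation
(≥ 85% empirical coverage at n = 15 cultures) rather than against the
tabulated textbook ranks.

Per-culture N_t values are not published, so absolute published rates are
not reproducible; relative rates are. Published fold changes were computed
from unrounded medians (e.g. the null's printed 5.7 vs 26.5/4.71 = 5.6 from
rounded medians), so exact reproduction of printed folds is asserted only on
rows where the printed medians carry enough precision (3.4 and 6.5).

Estimator calibration (simulated, 15-culture assays, expected loads 1–20
mutations per culture): the median-method estimate is within ~±15% of truth
in the median, comfortably inside the ±30% band asserted by the tests.

## Obligate-crossover viability model

Each homolog pair needs ≥ 1 crossover to direct MI disjunction. With
wild-type genome-wide means of 3, 8, 4 and 7 crossovers on chromosomes III,
VII, VIII and XV and the published double-knockout fold reductions (6.1,
7.2, 16.5, 11.4), the reduced means are 0.49, 1.11, 0.24, 0.61 — only
chromosome VII keeps ≥ 1 expected crossover. Crossover counts are modelled
Poisson (the minimal completion of a means-only argument), so
`P(achiasmate) = exp(−mean)`, and fold reduction is assumed uniform along a
chromosome.

An achiasmate pair disjoins correctly with probability `p_disjoin`
(distributive disjunction or centromere-pairing backup — the data do not
distinguish the mechanisms, so it is a free parameter, not an inferred one);
otherwise MI nondisjunction marks a uniformly chosen spore pair nullisomic
(dead) and the complementary pair disomic (viable by default — yeast
disomes germinate; togglable). Meiosis II and sister segregation are assumed
faithful. Background death applies independently per surviving spore. The
viable-spore distribution is computed exactly by dynamic programming over
the 16 spore-survival masks (exact for any realistic chromosome number) and
is cross-checked against an independent Monte-Carlo implementation.

## Synthetic meiosis generator

The generator emulates the study's dissection data:

* **Crossovers.** Per meiosis, chromosome and interval, the crossover count
  is Poisson with mean `m = d/50` per four-chromatid bivalent (an obligate
  single crossover makes every tetrad a TT, i.e. 50 cM). Each crossover
  joins one chromatid of each homolog, chosen uniformly and independently
  (no chromatid interference, no crossover interference); chromatid paths
  are resolved by traversal over the original strands, which makes
  disjoint intervals independent and reproduces the closed-form
  PD/TT/NPD probabilities (`TT = (2/3)(1 − e^{−3m/2})`,
  `PD − NPD = e^{−m}`) — tested against those forms at m = 0.4 and the
  1:4:1 limit at m = 10.
* **Pathways.** Crossing over is split into interference-dependent,
  interference-independent and residual classes with wild-type shares
  0.45 : 0.45 : 0.10. The study quantifies no pathway partition; these
  shares were fixed once so that zeroing both named pathways (the double
  knockout) retains 10% of wild-type crossing over — a 10-fold decrease,
  inside the published 6.1–16.5× range — and zeroing either single pathway
  retains 55%, the right order for the single knockouts. Genotype presets
  are just (interference, non-interference) multipliers: wild type (1,1),
  interference-pathway null (0,1), non-interference null (1,0), double
  (0,0).
* **True distances** per interval are the wild-type Perkins estimates
  recomputed from the packaged printed counts; whole-chromosome crossover
  means (3, 8, 4, 7) supply an unmapped remainder so achiasmate calls
  reflect the full chromosome, not just the marked region.
* **Gene conversion** is marker-local (no tracts): each marker × tetrad
  converts with probability 0.01 per meiosis (the mid-range of the
  published per-marker aberrant-segregation percentages), overwriting one
  random spore's allele.
* **Viability.** Achiasmate chromosomes are resolved with the viability
  model above; defaults `p_disjoin = 0.9`, disomes viable, background death
  0.08 per spore. These were chosen once from the published qualitative
  picture: wild-type viability is ~91–97% with essentially no achiasmate
  chromosomes (fixing background death), and double-knockout viability
  stays high (62%) despite most chromosomes lacking crossovers, which
  requires efficient achiasmate disjunction.
* **Fluctuation cultures** grow by synchronous doubling from 20 to
  20·2²⁰ ≈ 2.1×10⁷ cells with per-division mutation probability μ; mutant
  lineages double, mutation is irreversible, plating efficiency is 1. This
  reproduces the Luria–Delbrück P0 law and jackpot tail but not
  differential mutant fitness or phenotypic lag.
* **Determinism.** All randomness flows from one seeded generator;
  identical (config, seed) gives byte-identical files and manifests, and
  every written dataset carries a JSON manifest of realized crossover,
  conversion and NDJ events plus final tallies.

What the synthetic data do *not* emulate: crossover interference (a
gamma-renewal placement would be the natural extension; the published
analyses never estimate interference, so it is omitted), conversion tracts
and crossover-associated conversion, chromatid interference, dissection or
genotyping errors, and ascertainment quirks of real replica-plating. Tests
passing on synthetic data therefore validate the estimators under the
no-interference model, not the biology of interference.

A deliberate, realistic ascertainment effect does appear: conditioning
tetrad tallies on four viable spores enriches for meioses whose chromosomes
received crossovers, so the double-knockout preset's recovered fold
decrease (~8–9×) sits slightly below the generative 10× — the same
selection operates on real dissection data.

## Numerical choices and problem sizes

Root-finding uses bracketed Brent iteration; the delta-method variance is
floored at zero before the square root; CI lower bounds are floored at 0 cM.
Ties in spore order are meaningless by construction (dissection order is
arbitrary). Default analysis problem sizes — 2000 tetrads per genotype,
500 simulated assays of 15 cultures, 10⁵ Monte-Carlo meioses — were chosen
to keep every estimator's sampling error a small fraction of the effects
being checked while the full suite runs in seconds.

## Known limitations

* Published CIs (Stahl tool) are reproduced only in the sense of point-
  estimate containment; cumulative published values can differ from Perkins
  sums by ≲ 0.6 cM.
* One published single-spore cell (the double knockout's centromere-distal
  chromosome III interval) contradicts its own printed counts; the packaged
  fixture stores the count-implied value (3.6 cM, not 8.5), flagged in the
  data file.
* The viability model treats chromosomes independently; spindle-level
  coupling between simultaneous nondisjunctions is not modelled.
* Absolute mutation rates depend on unpublished per-culture N_t; only
  relative rates are reproduced.
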