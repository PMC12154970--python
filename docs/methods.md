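# Methods

## The generative model behind the synthetic cohorts

The cohort generator (`mthet.cohort`) encodes a two-step account of why
detected mtDNA heteroplasmies in blood rise with age:

1. **Cryptic mutation.**  For each substitution class *c* (six
   strand-resolved classes × two strands), a person of age *a* carries a
   Poisson number of cryptic somatic mutations with mean
   `a · rate_per_year[c] + rate_constant[c]`.  Each mutation falls
   uniformly over the class's possible sites genome-wide and receives a
   cell fraction from a Beta distribution concentrated near zero
   (default Beta(0.7, 60), mean ≈ 0.011) — present, but usually below
   detection in bulk.
2. **Clonal expansion.**  Clonal hematopoiesis (CH) status is Bernoulli
   with probability `logistic(-6 + 0.06·age)` (≈5% at 60, ≈14% at 70).  A
   carrier has one expanded clone with clonal fraction Beta(2, 8) (mean
   0.2); each of the carrier's mutations rides that clone with
   probability 0.5, in which case its bulk heteroplasmy *is* the clonal
   fraction.  Bulk HL otherwise equals the cell fraction (the mutation is
   treated as homoplasmic within its lineage; multi-clone structure and
   within-cell heteroplasmy are deliberately out of scope).

Sequencing is emulated per call: site depth DP ~ Poisson(mean mtDNA
coverage, default 2000×), alternate depth AD ~ Binomial(DP, HL), a call is
emitted only when AD ≥ 1, and the *observed* HL is AD/DP.  Nothing about
detection is imposed directly; the allele-depth QC threshold therefore
interacts with coverage exactly as in real callsets.

Default rates give the age-accumulating classes (A>G both strands, C>T
heavy) per-year rates 0.05/0.05/0.10 and the remaining classes flat rates
(C>T light 1.2 dominating), producing a realistic heavy:light C>T bias
and a mean detected burden of ~2–3 per person after QC.  A
`mutation_timing` switch replaces the age-linear accrual with an
age-independent ("embryonic") expected count, since bulk data cannot
distinguish mutations acquired during development and carried up by later
clonal imbalance from mutations acquired continuously with age; the
default is the age-linear reading.

Sibling pairs (optional) share "transmitted" variants drawn once per pair
with identical true HL in both siblings (Beta(1.2, 6), mostly 0.05–0.4);
their somatic variants are independent.  Sample metadata (contamination
estimates, QC pathology flags, smoking, ancestry, haplogroup) are drawn
at low, realistic rates so the sample-level filters have work to do.

What the generator does **not** emulate: read-level errors and NUMT
misalignment (the QC threshold is motivated by them but the simulator
injects no contaminating reads), haplogroup phylogenetics, multi-clone
CH, selection on mutations (the generator is neutral — which is exactly
what makes it a usable null for the dN/dS machinery), and realistic
demography.  Passing tests therefore show that the *estimators* behave as
designed under their assumed data-generating process, not that real data
satisfy those assumptions.

## QC conventions

* The Poisson detection threshold is the smallest integer *t* with
  P(X < t) ≥ q (strict inequality, q = 0.95), X ~ Poisson(λ); λ is the
  person's mean **nuclear** coverage by default, with
  `threshold_basis="mito"` available since a copy-number-dependent cutoff
  is the other defensible reading.
* "Homoplasmic recessive" recoding treats HL < 0.01, and missing
  genotypes at sites with ≥ 100× coverage, as homoplasmic for the
  reference allele — i.e. the variant is absent for counting purposes.
* The burden filter keeps SNVs with HL ≤ 0.95 (inclusive, following the
  threshold's statement as an inequality on HL) and AD ≥ t; indels are
  excluded by construction.  The common-variant filter keeps
  0.05 ≤ HL ≤ 0.95, both ends inclusive.
* The packaged blacklist ships the five published recurrent-artefact
  variants; the derivation rule (count inflation > 500% between the
  strict and lenient filters, > 30 detections) is provided as
  `derive_blacklist` on any pair of callsets rather than re-run, since the
  original derivation pooled two biobanks.

## Spectrum and selection conventions

* Ori is 16172–210, inclusive on both ends, wrapping the circular origin.
  Boundary positions are few; the inclusive reading is fixed here.
* Trinucleotide contexts wrap the circular genome; a context containing a
  placeholder base is flagged unusable and excluded from context tables.
  Context categories: 6 classes × 16 flank pairs × 2 strands = 192;
  collapsing strands (complementing the A-referenced classes) yields the
  standard pyrimidine-referenced 96 used for SBS signature comparison,
  which is run per strand by default (a pooled mode exists) because no
  canonical 192→96 mapping is fixed by the comparison itself.
* Normalisation denominators are computed for exactly the categories
  being tabulated (class-level or context-level), both are available.
* Consequences use the vertebrate mitochondrial code via Biopython's
  table 2.  Same amino acid (stops included) → synonymous; gained stop →
  pLoF; any other change (missense, stop-lost, start-lost) →
  nonsynonymous.  pLoF is excluded from both dN and dS by default, with a
  fold-into-nonsynonymous mode.
* dN/dS counts one record per (sample, variant): the sampling null
  resamples per-individual counts, so the observed statistic must count
  the same way.  Heteroplasmy bins default to [0, 0.05), [0.05, 0.2),
  [0.2, 0.5), [0.5, 0.95] and are configurable.
* The sampling null preserves every individual's per-class count and
  draws without replacement within an individual (different individuals
  may hit the same site).  Because dN/dS depends only on consequence
  *counts*, each per-individual draw is realised as a multivariate
  hypergeometric sample over {nonsynonymous, synonymous, other} —
  distributionally identical to explicit site sampling and much faster;
  `draw_null_callset` provides the explicit form.  The observed
  percentile uses mid-ranks by default; `randomize_percentile=True`
  breaks ties uniformly, which makes the percentile exactly uniform when
  the observed data are themselves a null draw (this is how the
  self-consistency check is run).

## Matched resampling

Controls are matched to the CH group on integer age years and sex, as R
(default 500) independently drawn sets, without replacement within a set;
exact multiset equality is asserted on every set.  The difference
statistic (CH minus control, per set) supplies the point estimate (mean
over sets) and SE (SD over sets); significance is a normal z test, with a
rank-based permutation p as an alternative.  The z test's size depends on
the control pool dwarfing the CH group: the between-set SD estimates the
sampling variance of a matched group mean *with* a finite-pool
correction, so when the pool is only a few times the group the test runs
anticonservative.  At biobank-like pool:group ratios (≥ ~50) the
empirical size at α = 0.05 is ≈ 0.05–0.06, which is what the calibration
test and the acceptance run measure.

Disease associations adjust for age, sex, age·sex, age², age²·sex, plus
ancestry-group and haplogroup indicators; ever-smokers are excluded and
ancestry groups with fewer than 3 cases dropped.  IVW effect-size
regression uses weights 1/SEx²·1/SEy² and no intercept (the
Mendelian-randomization convention; an intercept option exists).
Sibling 1 is the lower sample id by default ("chosen arbitrarily" needs a
deterministic reading; a randomised option exists).

## mtCN adjustment

log raw mtCN is residualised on: a natural cubic spline in blood draw
time (5 df, knots at quantiles), a natural spline in assessment date with
seasonal knots on a 3-month grid anchored at the earliest date, fasting
time clamped to [1, 18] hours as indicators, assessment center and month
indicators, and the supplied blood-composition columns (an explicit list,
since which variables are collinear is dataset-specific).  Blood values
beyond 4 SD are blanked per variable and rows with any missing covariate
dropped (not imputed).  The spline basis is the truncated-power natural
basis; because basis conventions differ across ecosystems, tests assert
residual properties (smooth-effect removal, variance reduction, zero
mean), never coefficients.  A display-scale variant adds back the
pre-adjustment mean of log mtCN and exponentiates.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 2,000–20,000 samples on the full
16,569-bp genome (possible-SNV enumeration is cached per genome), 500
repetitions for the dN/dS uniformity check (200-replicate nulls, 12
individuals × ~3 variants), and 1,000 single-cohort repetitions
(n = 2,000, ~1% CH) for the matched-test size — sizes chosen so every
statistical check has comfortable power while the whole suite stays in
the minutes range.  Degenerate inputs are reported, not guessed at:
dS = 0 flags the ratio undefined, empty comparison arms yield no
estimate, separated logistic fits are flagged without an estimate, and a
zero resampling SE with a nonzero difference reports p = 0 with a
warning.
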