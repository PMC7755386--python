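# Methods

## The encoding

A variant's geographic distribution code assigns one letter per group, in a
fixed order given by the grouping scheme: `u` where the tracked allele is
undetected, `R` where its frequency is positive but at most the threshold
*t*, and `C` where it exceeds *t*. Defaults: *t* = 5% (configurable; 1% is a
common alternative), five groups. The letter boundary is evaluated on exact
integer counts — a count *ac* out of *an* chromosomes is rare iff
*ac·q ≤ p·an* for *t = p/q* — so a frequency of exactly 5% is always `R`
regardless of floating-point representation, and the strict `>` rule for
`C` is applied uniformly on the data side and in the theory module.

Polarization: by default the globally minor allele is tracked (pooled
frequency ≤ 50%; a tie at exactly 50% tracks ALT, a deterministic,
VCF-native rule). Derived-allele polarization is available when an
ancestral-state annotation (INFO `AA` or an external map) identifies the
mutant allele; sites with unusable ancestral calls are skipped and logged.
Missing genotype alleles are excluded from both numerator and denominator,
so called-chromosome counts vary by site; half-calls contribute only their
called allele. Multi-allelic records and non-SNVs are skipped, not
decomposed. A singleton is a variant whose tracked allele has pooled count
exactly 1 — a count-based definition, so a single homozygous carrier (count
2) is not a singleton.

## Tallies, plots, subsetting

Code tallies are ranked by descending count with lexicographic tie-break.
The stacked plot draws codes bottom-up by rank; codes below a display
cutoff (default 0.5% of variants) are collapsed into a single gray
remainder block, and displayed proportions plus remainder always sum to 1.
Heatmap frequency bins are nonlinear to resolve rare variation —
{0}, (0, 1%], (1%, 5%], (5%, 10%], (10%, 20%], (20%, 50%], (50%, 100%] by
default, configurable — with the zero bin kept separate from arbitrarily
rare nonzero frequencies. Site lists for array subsetting accept BED
(0-based half-open, expanded to covered 1-based positions) or two-column
chrom/pos text (1-based); matching is on chrom+pos by default because probe
manifests state alleles inconsistently, with allele-aware matching as an
option.

## Pairwise spectra

Two individuals differ at a site when their unordered diploid genotypes —
equivalently their alternate-allele dosages — differ; phase is ignored.
Sites with a missing genotype in either individual are excluded (exclusion
avoids inflating differences). Each differing site is matched to the
reference table on chrom, pos and alleles; unmatched sites count toward
S_U and are treated as not globally widespread, so the widespread fraction
uses denominator S. The reference table should come from an independent
dataset to avoid ascertainment bias.

## The split model

Two Wright–Fisher populations of N diploids each diverge from a common
population of N diploids; an optional recent reciprocal admixture pulse
reassigns each sampled lineage to the other population with probability α
immediately before sampling. Mutation is infinite-sites; codes are computed
for the derived allele from its counts in samples of `n_sample` diploids
per population, and proportions are reported among sites segregating in
the pooled sample (pooled-absent and pooled-fixed classes excluded).

**Time units.** The scaled divergence time `t_over_2n` is measured in the
4N-generation drift units used by ms-style coalescent tools: at N = 2×10⁴,
the shallow scenario 0.05 corresponds to T = 4,000 generations and the deep
scenario 0.5 to 40,000. This calibration is what reproduces the package's
reference abundances (shallow split: CC ≈ 23.9%, RR ≈ 1.5%, RC+CR ≈ 5.8%;
with α = 0.02: RR ≈ 4.8%, RC+CR ≈ 9.5%); reading the same scaled times in
2N-generation units doubles CC to ≈ 28% and RR to ≈ 4.3% at α = 0 and is
not what this package's defaults mean. The single-population heuristics
below use plain generations and 2N genome copies, so no unit conversion is
hidden in them.

Two independent computation paths give the expected code distribution:

1. **Coalescent (default).** Replicate genealogies are simulated with
   msprime for the two samples; the joint allele-frequency spectrum is
   accumulated in branch-length mode, i.e. each genealogy contributes the
   exact expectation over mutation placement, so Monte Carlo noise comes
   only from the genealogies. Admixture is two mass-migration pulses at
   times ε and 2ε before the present (per-lineage reassignment; the O(α²)
   interaction of the two pulses is negligible at α = 0.02). With the
   default 4,000 replicates the standard error on the CC percentage is
   about 0.15 pp; the acceptance script uses 20,000 (≈ 0.07 pp).
2. **Diffusion grid (cross-validation).** The drift process is discretised
   as a Wright–Fisher population of `grid` genome copies (default 1,000)
   with time rescaled to preserve the scaled divergence. The ancestral
   standing variation enters with the neutral equilibrium spectrum
   (weight 2/i at derived count i, the discrete analogue of θ/x), is
   propagated through the exact binomial transition kernel raised to the
   divergence time, and is joined with the transient spectrum of
   post-split private mutations accumulated generation by generation.
   Sample-code probabilities are then computed per population-frequency
   pair through binomial sampling at the admixture-blended frequency.
   The grid discretisation biases CC upward by ≈ 0.5–0.7 pp at grid 800–
   1,000 relative to the coalescent path; the two paths otherwise agree,
   which is the dual-route check the tests enforce.

Single-population drift quantities: `typical_frequency_change` returns the
diffusion-scale standard deviation √(f(1−f)Δt/2N) — an allele at 25%
drifts by about ±10 pp over 0.05×2N generations, hence a likely interval
of roughly (15%, 35%). `extinction_probability` and
`conditional_mean_frequency` use the exact transition-matrix distribution
for 2N ≤ 2000 (matrix powers by repeated squaring for long horizons) and
seeded binomial Monte Carlo otherwise (standard error √(p(1−p)/reps)); the
extinction probability rises toward 1 − f₀ (the complement of the neutral
fixation probability) and the conditional mean frequency of a surviving new
mutation grows near-linearly in t for t ≪ 2N, inside the envelope f < t/2N.
`detection_power` is the closed form 1 − (1−f)^(2n).

## Synthetic data

The archetype generator draws each variant from a mixture of five code
archetypes — group-private singleton, group-private rare, rare shared by a
group pair, globally common, common in one group and absent elsewhere —
with default weights 0.35/0.25/0.15/0.20/0.05 chosen so that, as in large
sequencing cohorts, singletons are the largest class, private rare variants
dominate, and a substantial minority of variants are globally common.
Counts are drawn so the intended code holds *by construction* (e.g. a
private rare count is uniform on [1, ⌊t·2n⌋]); the generator returns the
ground-truth code per variant, and genotypes are written from the realized
counts, never re-sampled, so a VCF round trip reproduces the table exactly.
Default scale is 5 groups × 20 diploids and 10³–10⁴ variants, which keeps
the suite at seconds per test. What the generator does **not** emulate:
linkage disequilibrium, realistic site-frequency spectra within the rare
class, missing data patterns, or genotyping error — so passing tests
demonstrate correctness of counting, encoding and bookkeeping, not
robustness to real-data artefacts.

The coalescent generator reuses the split model as a data source (binary
infinite-sites mutations, ancestral allele = REF, so derived polarization
is exercised end to end). The mutation rate is set to a handful of sites
per genealogy to limit within-tree correlation; the end-to-end test that
the empirical tally matches the theoretical expectation allows a design
effect of 2 on the multinomial standard error for this clustering.

## Numerical and design choices

- Thresholds are exact rationals (`Fraction(repr(x))`, so `0.05` means
  1/20); all boundary comparisons are integer comparisons.
- Tie-breaks: rank ties in tallies are lexicographic; the 50% polarization
  tie tracks ALT.
- Degenerate inputs: an all-`u` code, an empty table (or empty after
  singleton removal), and an empty widespread-fraction denominator are
  errors; an identical pair of individuals yields S = 0 flagged degenerate
  rather than an error.
- Figures are pure functions of their inputs: sampling is seeded, the SVG
  hash salt is pinned and date metadata stripped, so vector output is
  byte-identical on re-run.
- Seeds: every stochastic routine takes an explicit seed; msprime seeds are
  reduced modulo 2³¹.

## Problem sizes

Defaults were chosen so a full test run completes in about a minute on one
CPU: 1,500–6,000 coalescent replicates in tests (20,000 in the acceptance
script), diffusion grid 800–1,000, split-dataset tests at 4,000–8,000
segregating sites, exact-matrix drift checks at N = 100.

## Known limitations

- The split model ignores growth, continuous migration and selection by
  design; it is a teaching-scale approximation, not a fitted demography.
- Rarefaction correction for unequal group sizes is not implemented; the
  detection-power function quantifies, but does not remove, the resulting
  asymmetry in `u` calls between groups of different size.
- Genotype likelihoods, phasing, structural variants and multi-allelic
  decomposition are out of scope.
- The diffusion-grid path trades a small discretisation bias for
  determinism; treat the coalescent path as the reference.
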