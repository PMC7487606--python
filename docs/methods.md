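# Methods

## Model and assumptions

The method treats epigenetic variation across a cohort as partially
organized by regulatory programs: if a regulator's activity varies across
samples, the epigenetic signal at that regulator's target regions covaries
with it. Given a loci × samples signal matrix and a per-sample target
variable, the analysis is two convex aggregations away from the raw data:

1. a per-locus association (feature contribution score, FCS) between the
   locus's signal vector and the target — covariance, Pearson, or Spearman;
2. a per-region-set aggregate of those FCS over the set's genomic regions.

Nothing in the scoring assumes normality of the signal; the association
metric carries all distributional assumptions. Covariance is preferred for
bounded [0, 1] methylation fractions because it weights loci by their
dynamic range; Pearson for count-like accessibility so peaks with very
different ranges score comparably; Spearman when the target is ordinal or
the relationship is monotone but not linear. `recommend_metric` encodes
this mapping but never overrides an explicit choice.

Coordinates are 0-based half-open throughout (BED convention); 1-based
single-position CpG tables are converted on read (position p → [p−1, p)).
Strand is ignored. Chromosome names match by exact string equality, with an
optional "chr"-prefix normalization flag at I/O time only — silent aliasing
produces false negatives that are harder to notice than a loud mismatch.

## Scoring details

**Nucleotide resolution** (single-CpG data): per region, the mean (or
median) FCS of overlapping loci; then the same statistic across regions.
Using the same statistic at both levels is the simplest symmetric reading
of "median as an alternative to the mean"; the choice applies jointly via
`stat=`. A locus inside two regions of a set contributes to both region
averages but is counted once in `n_features`. Regions without any locus
drop out of the outer statistic; a set with no covered region scores NaN
rather than raising, so database sweeps never abort.

**Region resolution** (peak data): one pooled weighted average over all
(data region, set region) overlap pairs with weight
`overlap_length / set_region_length`; a data region spanning two set
regions contributes one term per overlap.

**Absolute values** are applied to the FCS before any averaging by default
(`use_abs=True`): latent-factor and principal-component signs are
arbitrary, and opposite-signed loci would otherwise cancel. Signed scoring
remains available for supervised targets with a meaningful direction.

**Coverage filter.** Sets with fewer than `min_covered_regions = 100`
regions containing at least one locus are dropped — few-region scores are
dominated by locus-level noise. The synthetic fixtures used by the tests
and the acceptance script are sparser than a 450k array (about one locus
per kilobase, so decoy sets average ~80 covered regions of 200); analyses
on those fixtures therefore pass `min_covered_regions=1` explicitly while
the default stays tuned to real data densities.

**Per-sample region-set signal** (`region_set_signal_average`) averages raw
signal per region and then across regions, giving each covered region equal
weight regardless of its locus count — the summary used to relate a
region set to per-sample outcomes downstream.

## Unsupervised targets

`pca_targets` decomposes samples-as-observations, loci-as-variables.
Centering is on by default. `scale=True` divides each locus by its standard
deviation, making the decomposition equivalent to one on the correlation
matrix — recommended for count-like data, off for methylation. Loci with
any missing value are dropped before the decomposition (count logged).
Component signs are fixed by requiring each component's largest-magnitude
loading to be positive; with absolute-value scoring this is cosmetic, but
reproducibility requires a rule.

## Permutation inference

For each of `n_perm = 300` permutations, one shared shuffle of sample
labels is applied to **all** target columns jointly, FCS are recomputed,
and every surviving set is rescored. Only the target is shuffled — the
signal matrix keeps its inter-locus correlation, so each set's null
reflects its own internal correlation and coverage. The shared shuffle
(rather than independent per-target shuffles) preserves cross-target null
correlation and makes multi-target runs reproducible from one seed; draws
are Fisher–Yates permutations from one named `numpy` generator.

Each (set, target) null gets a gamma fit by the method of moments
(`shape = mean²/var`, `scale = var/mean`, unbiased variance). Gamma tail
p-values extrapolate beyond `1/(n_perm+1)`; the approximation is accurate
in the bulk but can overstate the significance of very small p-values, so
results record `p_source` and the conservative add-one empirical p
(`(1 + #{null ≥ obs}) / (1 + n_perm)`, never zero) is used automatically
whenever the fit is refused — negative scores (signed scoring), zero
variance, or nonpositive mean. No shift is attempted for signed-score
nulls; refusing the fit is preferred over guessing an offset.
Benjamini–Hochberg q-values are computed per target across all scored
sets; missing p-values propagate and do not count as tests. The 5% FDR
level is a reporting convention only — all q-values are emitted.

## Meta-region profiles

Each region is replaced by a `total_width = 14000` bp window centered on
`floor((start+end)/2)` and cut into `n_bins = 21` bins with rounded integer
boundaries that preserve total coverage; `n_bins` is forced odd so the
middle bin sits at offset 0. The bin count is this package's default; any
odd value ≥ 3 works. Loci enter bins by midpoint at nucleotide resolution
(exact for single-base loci); at region resolution each bin is scored by
the same overlap-proportion weighting as the set scorer. Per-bin values are
averaged within each region first, then across regions — the same nesting
as the score. Profiles are not symmetrized; left/right flank asymmetry is
informative. `profile_peak_statistic` summarizes center specificity as the
center-bin value minus the mean of the outermost `flank_bins` on each side.

## Synthetic data generator

The generator emulates the structure the method assumes, not any
particular assay platform. Per sample, a standard-normal latent factor
`z`; per locus, a latent signal `effect_size·z + N(0, noise_sd)` for loci
inside the planted regions and pure noise elsewhere, mapped to the
observed scale by a logistic squash around 0.5 (methylation — keeps the
bounded [0, 1] support that motivates covariance, without truncation
artifacts) or exponentiation (accessibility — positive, lognormal,
carried at region resolution with 200 bp data loci by default). Planted
regions are placed disjointly and uniformly; decoy sets uniformly with no
exclusion, so decoys can touch planted loci — spatial coincidence is part
of a realistic null and exercises the coverage filter honestly.

The canonical planted configuration is 100 samples, 20,000 background
loci plus 200 planted regions × 3 loci (500 bp regions), effect 1.0,
noise 1.0, 100 decoy sets × 200 regions on a 2×10⁷ bp synthetic
chromosome. The calibration and gamma-fidelity checks use a reduced null
configuration (2,000 loci, 50 samples, effect 0) so a thousand independent
replicates run in seconds; these sizes are the package's chosen test
conditions, large enough for the binomial tolerances asserted.

What the generator does **not** emulate: 450k probe design and dye biases,
array normalization, batch effects, chromosome structure (one synthetic
chromosome), CpG density patterns, or correlated background loci. Passing
tests therefore demonstrate correctness of the algorithms and calibration
of the inference under the stated generative model — not robustness to
real-data artifacts, which should be addressed upstream (normalization,
batch correction) as usual.

## Numerical choices and degenerate inputs

- Missing cells are handled pairwise-complete per locus; loci with fewer
  than 3 complete pairs get a missing FCS and are excluded from scoring.
  Pairwise-complete Spearman re-ranks the target within each locus's
  complete subset (vectorized fast path when a locus has no missing data).
- A constant target is an error for correlation metrics but yields zero
  covariance with a warning, so degenerate permutation shuffles cannot
  crash a run.
- Correlation FCS are clipped to [−1, 1] against rounding drift; tiny
  negative variances from cancellation are floored at 0.
- Gamma p-values are floored at the smallest positive float; a negative
  observed score yields p = 1 by convention (with a warning).
- Ranking ties are broken by region set name ascending, making output
  byte-stable; storage order of loci, regions, and database files never
  affects any score.
- All randomness (permutations, simulation) flows through
  `numpy.random.default_rng(seed)`; a fixed seed reproduces every output
  byte-for-byte.

## Known limitations

- With a precomputed FCS matrix (the multi-omics-factor workflow), the
  per-sample data needed to re-shuffle labels is bypassed, so no
  permutation test is possible; scores and ranks are produced with missing
  p-values.
- Gamma tail p-values below ~1/n_perm are extrapolations; compare
  competing sets by rank and treat extreme p-values as screening evidence.
- Overlapping region sets (e.g. two ChIP-seq experiments for one factor)
  yield correlated scores and p-values; BH correction does not model that
  dependence beyond its usual robustness.
- The weighted scorer normalizes by set-region length; a tiny set region
  fully covered by a broad data region carries the same weight as a broad
  region fully covered — intentional, but worth knowing when databases mix
  very different region widths.
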