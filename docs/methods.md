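# Methods

## The problem

When two closely related species (e.g. human and chimpanzee) plus an
outgroup (macaque) are profiled for gene expression across postnatal life,
per-gene species differences come in qualitatively different flavors.  A
gene may sit at a different constant level in one species throughout life
(*constitutive* divergence), or the *shape* of its expression-age trajectory
may differ between species (*developmental remodeling*, also called pattern
divergence or heterochrony).  `devodiverge` separates these modes, assigns
the divergence to lineages via expression-distance trees, and screens
trans-regulators (miRNAs, TFs) whose predicted targets concentrate and
anti-correlate within the remodeled gene set.

## Age scale

Expression is modeled against transformed age x.  Default:
x = log2(age_days + offset_species), with offsets equal to gestation length
(human 280 d, chimpanzee 224 d, macaque 165 d).  The offset keeps birth
(age 0) finite and aligns species on a comparable developmental origin; it
is configurable per species.  A life-history mode is available that first
maps each species' age onto a reference species' timeline through a
strictly monotone piecewise-linear interpolation of developmental landmark
pairs (linear extrapolation beyond the last landmark), then applies the
reference log2 offset.  Both modes are strictly increasing in age.

## Trajectory models

Per gene and species, expression is fit by ordinary least squares to
polynomials in x of degree 0..3.  Degree is selected by maximum adjusted R²
(default) or forward nested F-tests at α = 0.05; the degree is capped at
(#distinct x − 1) for rank-deficient designs.  The selected polynomial is
the *only* curve used in distances, interpolation and regulator-target
correlations; a cubic smoothing spline helper exists purely for plotting.
Species are compared on a common grid of G = 20 equally spaced points
spanning the intersection of the species' transformed-age ranges (a grid in
a region where every species has data avoids extrapolation).  Sensitivity
to G is exercised in the test suite, not in the results.

## Significance tests and calibration

Three nested F-tests drive gene typing:

* **age test** (per species): polynomial family vs. intercept.
* **differential-expression test** (per pair, ANCOVA): one shared
  polynomial over the pooled pair vs. per-species polynomials.
* **pattern test** (per pair): per-species mean-centered data; shared shape
  plus per-species intercepts vs. per-species polynomials.  Only the
  age-dependent (shape) terms are tested, so the p-value is exactly
  invariant to per-species constant shifts.

A deliberate design choice: all three tests compare the **full polynomial
family at the configured maximum degree** (capped by sample support) rather
than the data-selected degree.  Testing a data-selected model against the
null is anti-conservative and puts a point mass at p = 1 where degree 0 is
selected; with a fixed family the null distribution of every p-value is
exactly F, so the tests are exactly calibrated (verified: empirical
rejection at α = 0.05 within [0.04, 0.06] and Kolmogorov-Smirnov uniformity
on 2,000 pure-noise genes).  Degenerate fits (zero residual variance with
nonzero model df) return p = 0 with a warning.

Typing thresholds (defaults): significant p < 0.001, constant/absent
p > 0.01.

* **Type I** — age test p > 0.01 in *all* species and differential
  expression p < 0.001 in ≥ 1 pair (constitutive divergence, flat genes).
* **Type II** — age test p < 0.001 in ≥ 1 species, differential expression
  p < 0.001 in ≥ 1 pair, pattern p > 0.01 in *all* pairs (constitutive
  divergence, developmental genes).
* **Type III** — age test p < 0.001 in ≥ 1 species and some pair with both
  differential-expression and pattern p < 0.001 (developmental remodeling).

The bands are non-exhaustive by design; genes between bands stay
unclassified ("none").  False-discovery rates are estimated by permutation:
ages permuted within species for the age test; species labels permuted
within a pair (each sample keeps its own age) for the ANCOVA tests.
FDR = mean permuted significant count / observed significant count.

## Branch lengths and lineage ratios

Fitted trajectories are interpolated on the common grid; pairwise Euclidean
distances between curves feed the closed-form three-taxon additive
(neighbor-joining) decomposition

    b_H = (d_HC + d_HM − d_CM)/2,  b_C = (d_HC + d_CM − d_HM)/2,
    b_M = (d_HM + d_CM − d_HC)/2.

For pattern (type III) analyses each curve is mean-centered on the grid
first, so constitutive level differences contribute nothing — the branch
lengths then measure pure shape divergence.  Noisy distances can produce
negative raw branches; they are clamped at a floor of 1e-6 and flagged.
Genes with a clamped ingroup branch are excluded from ratio distributions
(and counted) since their log ratio would reflect the floor; no magnitude
truncation is applied to retained ratios.  Per gene set we report the
median of R = log2(b_H / b_C), a two-sided Wilcoxon signed-rank test of
median 0 (exact for n ≤ 25 without ties, normal approximation with
continuity and tie correction otherwise — spelled out because p-values
near thresholds depend on it), and a percentile bootstrap CI of the median
(1,000 resamples of genes, seeded).  A binary lineage test (binomial
against 0.5 on "human-outgroup distance exceeds chimpanzee-outgroup
distance", ties dropped) serves sparse designs where distances, not
branches, are trusted.

## Regulator screen

Two stages per regulator, given a focal gene set (typically type III) and a
background set (the other divergent types):

1. **Enrichment** — one-sided hypergeometric test of the regulator's
   predicted targets in the focal set, universe = focal ∪ background
   restricted to expressed genes.
2. **Correlation excess** — among enriched regulators, one-sided binomial
   test that the fraction of in-set targets with Pearson r below −0.75
   exceeds the background rate, which is the mean of that fraction over
   non-enriched regulators (a pooled-target variant is available).

Correlations use concatenated interpolated curves over the three species
("profile" mode, 3G points) or concatenated pairwise between-species
difference curves ("species_diff" mode, which removes shared age effects
and is invariant to adding the same curve to every species).  For TF-style
analyses the correlation sign flips: pass tail="positive" with cutoff
+0.9.  The distribution-level analysis uses a stricter |r| > 0.9 band;
both cutoffs are parameters with those defaults.

The number of enriched regulators expected by chance is estimated by
permuting the focal/background labels over genes with set sizes preserved;
the empirical p uses the add-one rule (1 + #{perm ≥ obs})/(1 + n_perm).
A correlation-excess distribution (per-bin target-pair density minus
non-target density; permutation null from resampled pseudo-target sets of
matched size) visualizes where the excess concentrates.  Transfection
validation reduces to a one-sided Wilcoxon rank-sum test that
target effect sizes (transfected minus control log2 expression, averaged
over cell lines upstream) shift downward relative to non-targets.

## Enrichment and sequence associations

Functional-category enrichment is the same hypergeometric machinery with
Bonferroni correction over the categories actually tested (those with ≥ 1
test-set member); the universe is test ∪ background with background
excluding test genes.  Specificity contrasts report set mean (or median)
of a per-gene metric (expression breadth, 0/1 neuron/glia membership)
minus the all-expressed-genes mean, with a percentile bootstrap CI over
set genes; the metric must cover ≥ 80% of the set or the result is
flagged.

Sequence associations are Spearman rank correlations (exact permutation p
for n ≤ 9, with average ranks under ties; tie-corrected approximation
above) between per-lineage expression divergence (the NJ branch length;
"total" = tree size) and per-gene sequence scores.  Conservation scores
are sign-flipped into divergence.  Binding-site density is adjusted for
overall conservation by OLS residuals before set contrasts.  Two
preprocessing steps support robustness analyses: equal-width-bin
subsampling that equalizes gene sets' mean-expression histograms (each bin
downsampled to the minimum count across sets; quantile bins were the
alternative, equal-width chosen as the common microarray practice), and
trimming of the upper 5% of mutation estimates (alignment artifacts
inflate the extremes; ties at the cutoff are broken by stable input
order).

## Synthetic data: what it emulates, and what it does not

The generator draws per-species ages log-uniformly over each species'
postnatal range (human 0–90 y, chimpanzee 0–45 y, macaque 0–28 y), giving
the early-life-heavy sampling typical of developmental studies; 15
individuals per species by default.  Gene trajectories are random
polynomials of degree ≤ 3 on the transformed-age scale, baseline levels
uniform in [6, 12] log2 units, iid Gaussian noise (σ = 0.1 default), and
per-species constant shifts with SD 1.0 for divergent types.

Type III genes carry a mean-free shape perturbation along a single random
remodeling axis per gene: the human curve is displaced +k·e·u(x) and the
chimpanzee curve −e·u(x), where u is RMS-normalized over the common age
span, e ~ 0.5·U(0.7, 1.3), and k is the configured human acceleration
(default 5.2).  Placing both displacements on one axis with opposite signs
makes the three pairwise curve distances exactly tree-additive, so the NJ
branch lengths identify the implanted per-lineage magnitudes and the
median 2^R recovers k.  Had the two lineages been perturbed in independent
random directions, Euclidean distances would not add along the tree and
the estimator would systematically overshoot k — a property of the
estimator on any data, not of this generator.  Orthogonalizing u against
the constant function makes type III divergence pure pattern divergence,
so mean-removed distances are the correct detector by construction.

Coupled regulators are type III features (same acceleration model) whose
target genes express `level − coupling × (regulator signal − regulator
level)`: the regulator's age-varying and species-divergent components are
fully inherited, giving strongly negative regulator-target correlations
(≈ −coupling/√(coupling² + noise²) ≈ −0.99 at the 0.8 default) — the
idealized signature of a dominant repressive regulator.  Decoy regulators
have ordinary trajectories and random target sets.  Sequence scores couple
to the implanted divergence through a Gaussian copula at |ρ| = 0.3,
positive on the chimpanzee/macaque lineages and negative on the human
lineage; binding-site densities rise with conservation and with type III
membership.

Not emulated: probe-level artifacts, batch effects, count noise
(RNA-seq), partially overlapping sample sets between mRNA and miRNA
platforms, regulators with many weak targets, or target-prediction error.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability under idealized conditions, not performance
on real microarray data.

## Numerical choices

* Zero-residual tolerance in F-tests: 1e-12 relative to the response's
  total sum of squares.
* Degree-selection improvements must exceed 1e-12 (adjusted R²) to avoid
  tie-flipping on noiseless data.
* NJ branch floor 1e-6; ratio-unusable genes excluded and counted.
* Quantile normalization assigns tied values the mean of the reference
  values at their tied ranks, making the procedure idempotent.
* TSV readers use round-trip float parsing so write/read cycles are
  bit-exact.
* All randomized procedures (bootstrap, permutations, generator) take
  explicit seeds and use `numpy.random.default_rng`.

## Problem sizes used in the validation suite

The packaged tests and the acceptance script run the pipeline at 200 genes
per divergence type (800 total), 15 samples per species, σ = 0.1, 2,000
genes for null calibration, 100 seeded replicates for CI coverage, and 20
seeded screens of 3 implanted regulators among 50 decoys — sizes chosen to
give tight Monte-Carlo error on every property while keeping the whole
suite runnable on a laptop in a few minutes.

## Known limitations

* The pattern test assumes the polynomial family is rich enough for both
  species; shape divergence beyond cubic is invisible.
* Branch ratios are noisy for genes with small pattern divergence; the
  clamp-and-exclude rule discards those genes from ratio distributions,
  which can bias set medians if clamping is asymmetric between lineages
  (both the exclusion count and the raw trees are reported).
* The screen's background rate estimate degrades when non-enriched
  regulators have very few in-set targets; with a zero background rate and
  nonzero observed count the binomial p is reported as 0 with a flag.
* Permutation FDR is a ratio estimator; with very few observed significant
  calls it is unstable and is flagged undefined at zero.
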