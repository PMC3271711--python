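# Methods

## The membership model

A (subject, habitat) series is the day-ordered list of sampling events for
one body site of one person; consecutiveness is defined over sampling
events, not calendar days, so an uncollected span does not break a run. For
each OTU with any reads in the series we compute

* `n_observed` — timepoints with count > 0;
* `max_run_obs` — detections inside the best *gap-tolerant* stretch. Writing
  the detection days as positions `t_1 < t_2 < …`, consecutive detections
  belong to one stretch iff `t_{k+1} − t_k <= 2` (a gap of 2 means exactly
  one zero day in between, which is tolerated because both flanks are
  detections); a gap of 3 or more means at least two consecutive zeros and
  always breaks the stretch. The statistic counts detections, not the
  stretch's span, so `consecutive_fraction = max_run_obs / n_observed <= 1`.

Label precedence is core > persistent > transient > other, which makes the
partition well defined; the thresholds (20/90 for persistent, 60/75 for
transient) guarantee persistent and transient are disjoint because
0.90 > 0.75. Two readings of gap tolerance are implemented: the default
allows any number of *isolated* zeros inside one stretch (the weakest
reading of "a zero count at a single timepoint"); `single_gap_per_run=True`
allows at most one. The default was chosen because the tolerance is stated
as a per-timepoint condition; the flag exists because the stricter reading
is also defensible.

The G-test uses `G = 2 Σ O ln(O/E)` over non-zero observed cells of the
2 × T table of per-class OTU counts, with `df = T′ − 1` (taxa with non-zero
column totals) and no Williams/continuity correction. The rarefaction
jackknife compares each iteration's persistent-group composition against
the full-data composition (not iteration vs iteration); an iteration whose
persistent set is empty is counted as significantly different, since an
empty composition is maximally discordant.

## Core curves

The denominator at every threshold is the number of OTUs observed at least
once *within the subsampled sample set*, so `fraction(1) = 1` and curves
from different sample types (equalized to the same `n_subsampled`, default
130) are directly comparable. Pooled sample types ("S1:*", "*:*") draw
uniformly from the pooled set; stratified drawing per habitat is available
via a flag but is not the default, because equalization is about the total
number of observations, not their layout.

## Beta diversity

Unweighted UniFrac is computed branch-wise: one postorder pass collects,
for every branch, a boolean presence vector over samples (any descendant
tip detected); the pairwise distance matrix then follows from two matrix
products (`shared = (L·B)ᵀB`, `union = tot_i + tot_j − shared`). Two
samples with no occupied branches at all are assigned distance 0 (this
arises only for all-zero columns, which rarefaction never emits).

PCoA is classical scaling: eigendecomposition of the double-centered
`−½D²`, coordinates only on eigenvalues above `1e-10` relative tolerance;
negative eigenvalues are reported unchanged (no Lingoes/Cailliez
correction), and proportions of variance are taken over the positive
eigenvalues. Procrustes `M²` is computed on centered, unit-Frobenius-norm
configurations as `1 − (Σ singular values)²`, minimizing over translation,
rotation/reflection and isotropic scaling; the default uses the first 3
principal-coordinate axes. All permutation p-values (Procrustes, Mantel)
use the add-one estimator `(1 + #{as-or-more-extreme}) / (1 + n_perms)`, so
999 permutations bound p below at 0.001; the Mantel-style test is
two-sided on |r|. The within/between t-test pools each unordered sample
pair once and defaults to the pooled-variance statistic with a one-tailed
alternative (Welch via `equal_var=False`).

## Mislabel detection

The ensemble is bagged unlimited-depth CART trees with `sqrt(features)`
random feature subsetting per split — 2,000 trees by default, the only
ensemble hyperparameter the procedure fixes. Posteriors are out-of-bag vote
fractions (averaged class probabilities behind `average_probabilities`);
with unlimited-depth trees the two nearly coincide. Features are rarefied
counts, not relative abundances, and left/right palm are merged into one
"skin" class before training. Flagged samples are only reported; dropping
them from downstream analyses is an explicit downstream choice.

## The synthetic generator

`synth.generate_dataset` emulates a multi-subject, multi-habitat daily
series: per habitat it plants 10 core, 30 persistent, 30 transient and 200
background OTUs (defaults), assigns each OTU a log-normal baseline relative
abundance (medians: core 2%, persistent/transient 0.5%, background 0.02%;
log-sd 0.5–1.0) with day-to-day log-normal noise (log-sd 0.3), and draws
reads multinomially at the regime depth (500 / 5,000 / 10,000 are the
depths the analyses use), which produces realistic depth-driven dropout.
Presence structure: core OTUs occupy every day; persistent OTUs occupy one
contiguous window covering 30–85% of the series (never all of it);
transient OTUs occur in 4–6-day bursts separated by two absent days, so
their occupancy is ~0.7 but no stretch holds more than a small fraction of
their observations; background OTUs are independent Bernoulli(0.05) per
day. Habitat pools are disjoint and sit on separate long-stemmed clades of
a random bifurcating tree (exponential branch lengths), so habitats are
phylogenetically distinct; subjects carry each non-core OTU with
probability 0.7, which makes between-subject distances exceed
within-subject ones under unweighted UniFrac. Optional features:
`palm_coupling` (right-palm OTUs reuse left-palm presence time-courses with
the given probability, emulating microbial exchange between hands),
`class_abundance_sd` (a shared per-taxonomic-class log-abundance offset, so
shallow sequencing removes whole classes rather than a random thinning of
each group — this is what lets a depth-500 jackknife genuinely destabilize
the *composition* of the persistent group), an overdispersion parameter
(Dirichlet-multinomial) and planted mislabels, implemented as habitat-label
rotations within a (subject, day) group across distinct merged classes so
that sample-key uniqueness is preserved and every planted error is
detectable in principle.

What the generator does *not* emulate: sequence-level error, chimeras and
primer bias (the unit is the OTU count); taxa shared between habitats;
seasonal or successional trends; autocorrelated abundance dynamics beyond
the planted presence structure. Recovery results on synthetic data
therefore demonstrate the correctness and statistical behaviour of the
procedures under the planted model, not their error rates on real
communities, where detection-limit effects and shared taxa blur the
category boundaries.

## Numerical choices and problem sizes

Rarefaction draws without replacement via the multivariate hypergeometric
distribution; samples below the requested depth are dropped and logged,
never padded. The prevalence filter uses presence with a ceiling on
`min_fraction × n_samples`, so "1% of samples" is conservative at small n.
Every stochastic routine takes an explicit integer seed; derived seeds come
from `numpy.random.SeedSequence` and stay below 2³¹. Ties in the
gap-tolerant run (several equally long stretches) are irrelevant because
only the maximum count is used. Degenerate inputs fail loudly: empty
series, all-zero G-test margins, unmatched Procrustes ids, thresholds
outside a curve.

Test and verification sizes were chosen to give tight statistical checks at
interactive runtimes on one CPU: 10,000 random vectors for the run-statistic
oracle, 1,000 random 8-tip trees for the UniFrac oracle, 1,000 random 2 × T
tables for the G-test, 100 Euclidean configurations for PCoA, 200
replicates × 999 permutations for the Procrustes null calibration, 5 seeds
of the 4-habitat × 130-day recovery benchmark, 100-iteration jackknives,
and 3 seeds of the 504-sample × 2,000-tree mislabel benchmark.
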