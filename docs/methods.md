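# Methods

## Connectivity model

Let X be the region × time matrix of one participant's pooled,
normalized runs. The connectivity between regions i and j is their
partial correlation given all remaining regions: both series are
residualized by ordinary least squares on a design containing an
intercept, every other region's series, and any confound regressors,
and r is the Pearson correlation of the two residual series. For a
Gaussian process with covariance Σ and precision Ω = Σ⁻¹ this equals
−Ω_ij / √(Ω_ii Ω_jj), which is why the synthetic generator plants
structure directly on the precision scale.

Two implementation routes exist and are kept deliberately separate:

* `partial_corr_pair` runs the literal per-pair least-squares
  residualization (`numpy.linalg.lstsq`).
* `partial_corr_matrix` computes the same OLS algebra for all pairs at
  once via the Schur complement of the "other regions" block of the
  Gram matrix of centered series (confounds are projected out first;
  by Frisch–Waugh both shortcuts are exact, not approximations).
* `partial_corr_from_precision` (normalized negative inverse sample
  covariance) is a *diagnostic oracle only*; tests assert the two
  routes agree to ≤ 1e−8 on well-conditioned inputs, and it never
  replaces the regress-out estimator in the pipeline.

Estimation requires T > p + c + 2 timepoints (hard error) and warns
below 30 residual degrees of freedom. With the study layout — 25
regions, 6 × 128 = 768 volumes — the problem is comfortably
well-posed. Group matrices are entrywise means of participant matrices
on the raw r scale; a Fisher-z averaging mode exists but is off by
default, since downstream statistics are rank-based and the flags are
defined on raw r.

## ROI extraction

A region's sphere contains every voxel whose *center* lies within the
radius (inclusive, ≤ r, with a 1e−9 mm tolerance against floating
ties) of the region's MNI peak; membership is decided in mm space
through the image affine, so anisotropic or rotated grids work
unchanged. On a 3-mm isotropic grid a 6-mm sphere centered at a voxel
center contains 33 voxels (the integer offsets with
9(i²+j²+k²) ≤ 36). The region signal is the unweighted voxel mean per
volume.

"Normalization per run" is per-region z-scoring within each run
(sample sd, ddof = 1): it removes both run-level offset and run-level
scale, which is the point of discounting global signal differences
between runs; a center-only mode and an optional linear detrend per
run (default off — a mild stand-in for slow-drift removal, not a full
high-pass filter) are provided. A zero-variance series is a hard
error: flat extractions indicate a broken mask, never data. Dummy
volumes are assumed already absent from the inputs; the reader never
drops volumes silently. Runs are concatenated after normalization and
the boundaries are retained, both for audit and because the
randomized-null control permutes each region's series *within* run
boundaries (preserving run structure while destroying cross-region
temporal alignment).

Whether per-participant matrices should be estimated on concatenated
runs or per run and then averaged is not determined by the method
itself; the pipeline default is concatenation (768 volumes), and
`matrix_from_runs` accepts any subset of runs for sensitivity checks.
Similarly, whole-run series are used for every condition regime rather
than condition-restricted time windows; the generator's run-level
state switching matches that default, and a trial-level switching mode
exists for window-based analyses.

## Group statistics

* **Similarity**: Spearman's R_S between the r-value vectors of two
  group matrices over a pair subset (within- or between-network pairs,
  or all), average ranks for ties, two-sided p from the large-sample t
  approximation; an exact permutation p is available for n ≤ 10.
  Rank correlation is used because r-values across heterogeneous pairs
  are far from Gaussian.
* **Flags**: a pair is *enhanced* when r strictly exceeds the 0.20
  threshold in every compared group matrix (by default among
  between-network pairs). *Suppression* has no canonical formula; the
  declared convention here is symmetric with enhancement: the
  reference matrix must exceed the threshold and every target group
  must fall to ≤ it (default among within-network pairs). The two
  conditions are mutually exclusive for one comparison by
  construction. The threshold is configurable; 0.20 is the package
  default in r units.
* **Network membership**: for a network k, *specificity* is a
  two-sided Wilcoxon rank-sum test of within-k r-values against the
  r-values of pairs linking k to any other network, and *sensitivity*
  tests within-k against the within-r of all other networks (a
  non-rejection there is the desired outcome — the block is as strong
  as the established ones). W is reported as the rank-sum of the
  within-network sample (converted from the Mann–Whitney U given by
  scipy; W = U₁ + n₁(n₁+1)/2), and the result object enforces the
  attainable rank-sum range.
* **Behavior**: the paired contrast compares each participant's
  unweighted mean over the three harder conditions (Pas+, Pot, Pot+)
  with the mean over the three easier ones (Act, Act+, Pas); control
  and one-argument conditions are excluded. Group-vs-group contrasts
  on a single condition use an unpaired two-sample t-test. No
  multiple-testing correction is applied across these tests by
  default, matching how such analyses are conventionally reported; a
  Bonferroni correction is a one-line wrapper if needed for reuse.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
with full ground truth:

* **Design**: 4 trials × 8 conditions per run, 6-s stimulus + 2-s
  blank, TR = 2 s → 256-s runs of 128 volumes; condition order is
  block-randomized (each consecutive block of 8 trials holds every
  condition once). 6 runs per participant; groups of 16/9/9.
* **Series**: innovations ~ N(0, Ω_state⁻¹) filtered by a per-region
  AR(1) (φ = 0.3; AR filtering rescales the contemporaneous precision
  but leaves partial correlations unchanged), plus a task component —
  condition boxcars convolved with a canonical double-gamma HRF (peak
  gamma shape 6, undershoot shape 16, ratio 1/6), region amplitudes
  0.2–0.6 innovation-sd units, harder conditions 1.3× — plus white
  measurement noise (sd 0.3). Measurement noise attenuates estimated
  partial correlations by roughly the signal-variance fraction
  (~0.93 per pair here); the planted edge magnitudes leave enough
  margin around the 0.20 flag threshold that the attenuated values
  stay on the correct side.
* **Planted structure** (illustrative constants, not empirical
  values): Ω has unit diagonal and −p_ij off-diagonal, so p_ij *is*
  the population partial correlation. Within each network, consecutive
  catalog regions form a chain with strengths cycling through
  0.10–0.34 (values avoid the 0.16–0.24 window so no edge sits near
  the flag threshold). The harder state adds the two cross-frontal
  between-network edges L_F3t–L_F3op/F3t and L_F3op/F3t–L_LPMC at
  0.32 (enhancement) and collapses the two within-network pathway
  edges L_LPMC–L_AG and L_F3t–L_pSTG/MTG from 0.34 to 0.06
  (suppression). All remaining pairs get a reproducible ±0.04
  "noise floor" drawn from the structure seed — this is what makes
  even near-zero edges rank-reproducible between groups sharing a
  structure, and is the feature the between-network similarity
  statistic keys on. Both state matrices are verified positive
  definite at construction (min eigenvalue > 0.05, typically ≈ 0.4).
  The "combined" regime uses the mean of the two state precisions.
  A separate random-structure generator (edge probability 0.1,
  strengths 0.08–0.32, off-diagonal shrinkage to conditioning) supplies
  the no-shared-structure control.
* **Behavior**: per participant × condition, error % from a
  [0, 100]-truncated normal (sd 8) and RT from a 200-ms-truncated
  normal (sd 250 ms). Condition means plant a +15 % / +500 ms
  harder-minus-easier contrast; patient groups get extra error under
  the potential-sentence conditions (+12 % lpmc_f3 on Pot/Pot+;
  +8/+14 % extra on Act+/Pot/Pot+). Truncation at 0 inflates low error
  means, so the realized paired contrast is ≈ +13 % rather than the
  nominal +15 %; the power checks use the realized generator, not the
  nominal number.
* **Volumes**: `render_volumes` paints each region's series into its
  6-mm sphere (plus voxel noise) on a caller-supplied grid, erroring
  on overlapping spheres; with zero noise, extraction is exactly
  lossless, giving the end-to-end oracle for the ROI stage. The
  packaged 25 coordinates have a minimum center separation of
  ≈ 17 mm, so 6-mm spheres never overlap on the real layout.
* **Seeding**: every stream derives from
  `default_rng([master_seed, …tags])` with fixed per-group,
  per-participant, per-run tags; identical seeds reproduce series
  bit for bit.

## What the synthetic cohort does and does not show

The generator reproduces the *statistical* conditions of the study —
sample sizes, run structure, network-block precision structure,
load-dependent edge changes, behavioral effect directions — so passing
tests demonstrate that the pipeline recovers known structure at the
study's scale and noise level. It does not emulate spatially
correlated physiological noise, motion, lesion-induced signal dropout,
susceptibility artifacts, or hemodynamic variability across regions;
empirical R_S values from real cohorts are therefore not reproduced,
only the qualitative contrast between shared-structure similarity
(high within-network R_S), independent structures (R_S ≈ 0), and
time-randomized nulls (R_S ≈ 0).

## Problem sizes and numerical choices

The recovery suite runs 20 replicates of each scenario at full cohort
scale (16 + 9 participants × 6 × 128 volumes; flags additionally use
easier/harder state cohorts), which completes in about a minute on one
CPU; the large-sample population check uses a single 100 000-volume
run. Cholesky factorization is used both for sampling (of Σ) and for
the per-pair Schur complements (of the Gram submatrices); a failed
factorization surfaces as a collinearity error naming the pair.
Estimated r is clipped to [−1, 1] against floating drift, and matrix
symmetry/unit-diagonal invariants are enforced at construction. Ties
in rank statistics use average ranks throughout.
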