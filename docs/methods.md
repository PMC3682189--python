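# Methods notes

This note records the modelling assumptions, default parameters and
numerical choices behind `mtldecode`, and what the synthetic tests do and
do not establish about real data.

## Generative model of a run

A simulated run is

```
Y[v, t] = A * S[v, t] + d * t + e[v, t],      e ~ N(0, sigma^2) i.i.d.
```

where `A` is the signal amplitude (in units of the noise SD `sigma`),
`d` the linear scanner-drift slope per volume, and `S` the planted
haemodynamic signal. Per trial, the neural drive is a boxcar spanning the
7 s recall window, convolved with the canonical HRF on a fine grid
(TR/32) and sampled at the volume times.

* **Signal-bearing ROIs**: each memory class `c` has a fixed spatial
  pattern `p_c[v] ~ N(0, 1)` over the ROI's voxels, drawn once per
  subject; trials of class `c` drive `A * p_c[v]`.
* **Signal-absent ("sclerotic") ROIs and all out-of-ROI voxels**: every
  trial drives the same fixed spatial profile `u[v] ~ N(0, 1)`,
  regardless of class. These regions are just as "active" as
  signal-bearing ones in the univariate sense; only the *pattern*
  information differs, which is exactly the dissociation the analysis is
  meant to expose.

Class patterns are i.i.d. normal with no spatial autocorrelation; ROIs
are axis-aligned ellipsoids. Neither choice aims at anatomical realism —
the generator reproduces the statistical structure the decoder assumes
(stable per-class patterns, HRF dynamics, drift, stationary Gaussian
noise), not MR physics. Motion, physiological noise, field inhomogeneity
and inter-subject anatomical variability are deliberately absent, so
passing tests demonstrate correctness of the analysis machinery, not
expected effect sizes in patients.

### HRF

The canonical HRF is the double-gamma difference
`g(t; 7, 1) - g(t; 17, 1) / 6` (unit-scale gamma densities), i.e. peak
at exactly 6 s, undershoot near 16 s, peak:undershoot ratio 6, support
effectively [0, 32] s, peak-normalised to 1. The gamma *shapes* are
`delay + 1` so each lobe's mode sits at its named delay. Parameters are
config-overridable.

### Trial timing

Each trial is cue (default 3 s) + recall (7 s) + a single configurable
inter-trial gap that collapses the press window tail, the two rating
screens and the rest period. The default gap is 13 s (≈1.5 s fixation +
~7.5 s self-paced ratings + 4 s rest), giving a ~23 s trial; only
recall-window volumes are analysed, so the gap's exact decomposition is
immaterial. The run starts with 6 dummy volumes plus a 2 s settle before
the first cue.

### Behaviour

With exclusion rate `r`, each trial is independently made excludable
with probability `r`, by one of three mechanisms chosen uniformly: press
before 5.5 s, press after 10 s or absent, or a vividness/accuracy rating
below 3. Non-excludable trials draw latency from U[5.8, 9.5] s and
ratings from {3, 4, 5}.

## Preprocessing choices

* Chain order: discard dummies → smooth → detrend → HRF-convolve →
  shift onsets → extract. Onset bookkeeping is re-referenced so volume 0
  is the first retained volume.
* Smoothing uses nearest-neighbour boundary replication so edge-of-ROI
  voxels are not deflated toward zero.
* HRF convolution of the data is full causal convolution truncated to
  the series length — no mirror padding, no future leakage (output at
  volume *t* depends only on volumes ≤ *t*).
* Onset→volume mapping is `floor(onset / TR)` (the volume containing the
  onset), then shifted by `round(delay / TR)` volumes with half-away-
  from-zero rounding (12 s at TR 3.5 s → 3 volumes).
* The 4 extracted volumes are averaged into one pattern per trial by
  default — one sample per trial is the natural unit when the CV fold
  count equals the trial count. Per-volume rows are available via
  `average=False`.
* Boundary reading of the exclusion rules: a press at exactly 5.5 s or
  10.0 s and a rating of exactly 3 are *included* (the rules exclude
  strictly-outside values).

## Decoding choices

* **Codebook**: the exhaustive ECOC code, `2^(k-1) - 1` dichotomies; for
  3 classes this coincides with one-vs-rest. Rows are pairwise distinct,
  no constant columns.
* **SVM**: linear kernel, soft margin, fixed `C = 1`, LIBSVM
  implementation. The high-throughput inner loop calls the LIBSVM
  binding directly (the high-level wrapper's per-call validation
  dominates runtime at these problem sizes); a test asserts decision-
  value agreement with `sklearn.svm.SVC` to 1e-6. The LIBSVM stopping
  tolerance defaults to 1e-3 and is exposed for tighter fits.
* **Sphere scoring**: nested leave-one-trial-out within the training set
  (default). Nested CV rather than plain training accuracy because, at
  these dimensionalities, most spheres separate the training set
  perfectly and training accuracy cannot rank them. Training-accuracy
  scoring remains available (`scoring="train"`).
* **Degenerate nested folds**: if a nested fold's training set loses a
  class, the dichotomy columns with an empty side are dropped and
  prediction uses the remaining columns (so 3-trial sets still yield 3
  scored folds); a fold with no trainable column is skipped.
* **Tie-breaks**, all deterministic: equal sphere scores → lowest centre
  linear index; equal Hamming distances → lowest class label; decision
  value exactly 0 → +1.
* **Searchlight radius** is measured in voxel lattice units; an interior
  sphere of radius 3 contains 123 voxels.
* Within one CV fold, spheres with identical member sets share one
  cached score (pure memoisation; border-truncated spheres in small ROIs
  often coincide).
* Single best sphere per fold (not a union of top spheres); union-of-top
  selection was considered and left out to keep the selected feature set
  auditable per fold.

## Statistics choices

* Chance is the exact 1/3, never the rounded 33%.
* The RM-ANOVA is the classical univariate decomposition with subject as
  random factor, each effect tested against its own effect-by-subject
  interaction, no sphericity correction (hemisphere has 2 levels, so the
  interaction's correction would matter only for extreme non-sphericity
  across regions). All-equal cells return F = 0 by convention rather
  than 0/0. The implementation is cross-checked against statsmodels'
  `AnovaRM` to 1e-8.
* Pairwise contrasts default to two-tailed; tests against chance are
  one-tailed (a decoder cannot meaningfully perform below chance).
* `paired_t` on identical vectors returns t = 0; constant *non-zero*
  differences raise (zero-variance denominator).
* Dice of two empty masks is defined as 1.0 with a warning.
* No multiple-comparison correction; the conventional threshold is
  p < 0.05 throughout.

## Seeding and reproducibility

One master seed drives a whole experiment. Subject seeds come from
`SeedSequence([master_seed, subject_index])` (first 31 bits), and within
a subject the schedule, behaviour, patterns and noise use independent
child streams, so changing one stage's options cannot perturb another's
draws. Identical config + seed reproduces bit-identical runs, decoding
results and output-file hashes (recorded in the run manifest).

## Problem sizes used in the test suite

The statistical tests run at deliberately small "micro" scales chosen so
the whole suite executes quickly on a single CPU while keeping every
stage of the real pipeline in play: grids of 16×16×10 to 16×22×8 voxels,
ellipsoid ROIs of ~11 voxels (whose radius-3 searchlights coincide,
making selection cheap but still exercised), 36 trials (12 per class)
for single-ROI calibration and signal-recovery checks, and 18 trials
(6 per class) for the 9-subject, 6-ROI cohort dissociation checks. The
generator defaults themselves remain at the emulated design's values
(3 classes × 20 trials, TR 3.5 s, 7 s recall).

## Known limitations

* The nested-LOTO sphere scores are computed per outer fold from
  scratch; for ROIs with hundreds of voxels this is O(n²·voxels) SVM
  fits per ROI and becomes slow — acceptable for the intended desk-scale
  analyses, not optimised for whole-brain searchlight mapping (a
  non-goal).
* Leave-one-out cross-validation of classifiers on null data is known to
  show a small below-chance bias when the held-out trial's class becomes
  the training minority; at the suite's trial counts the effect is
  within the calibration tolerances, but analysts should prefer the
  permutation calibration over the nominal 1/3 when trial counts are
  very small.
* The generator's exclusion mechanism flags trials independently; real
  behavioural exclusions cluster (fatigue, drowsiness), which is not
  modelled.
* Inputs are assumed motion-realigned and distortion-corrected; the
  package performs neither.
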