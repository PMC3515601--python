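# Methods

## The problem

Two-class multivariate pattern analysis (MVPA) of brain-imaging data
asks not only *whether* two stimulus conditions or brain states can be
decoded from a data matrix, but *where* the discriminative information
lives. Classifier-driven feature selection answers the first question
with a small sufficient subset; pattern localization needs *all*
informative features, however weak, split by the condition they prefer.
This package implements a sparse representation-based pattern
localization (SPL) pipeline for that purpose: sparse regression weights,
backward recursive feature elimination, cross-validated selection
frequencies, and nonparametric permutation thresholds.

## Model and procedure

The data are a matrix `A` (t rows = time points or trials, m columns =
voxels/pixels) and a label vector `y ∈ {+1, −1}^t`. One stage per
module:

1. **Weights** (`sparse_weights`). The primary weighting is the
   minimum-L1-norm solution of the exact regression

       min ‖w‖₁  subject to  A w = y,

   solved as a linear program after the substitution `w = u − v`,
   `u, v ≥ 0` (HiGHS, equality constraints passed exactly — no
   ε-relaxation). For an underdetermined system the optimum is a vertex
   with at most t nonzeros; the sign of each nonzero weight indicates
   the class whose rows the feature's activity tracks. A linear
   soft-margin SVM (hinge loss, C = 1; the primal coefficient vector)
   and univariate Pearson correlation serve as dense comparison
   weightings. Weights below `1e-8 · max|w|` count as zero; when the L1
   minimizer is degenerate any optimal vertex is accepted.

2. **Recursive search** (`recursive_search`). Within one training fold:
   fit weights, remove the k largest-positive and k smallest-negative
   features (recording them in the class +1 / class −1 sets), then
   decode the remaining features with a linear SVM under an inner
   cross-validation. The loop stops the first time decoding accuracy
   falls to the chance threshold (50% for balanced two-class data; the
   terminating iteration's selections are kept), when nothing is
   selectable, or at the safety cap `floor(m / 2k)`. Removal is
   permanent, so a feature is selected at most once per fold, and
   features correlated with already-removed ones surface in later
   iterations — the mechanism by which the union over iterations
   approaches *all* informative features. The inner CV uses up to 20
   folds capped at the row count (on 19 training rows this is
   leave-one-out), stratified whenever the fold count permits; a
   training split that loses a class contributes chance predictions.
   k defaults to 2 at the 300-feature simulation scale; ~25 per class
   is appropriate at fMRI scale and ~100 per class at optical-imaging
   scale.

3. **Probability maps** (`localization`). The outer K-fold partition is
   contiguous by row (a blocked time-series reading; shuffling is an
   explicit option) with the remainder spread over the leading folds.
   Each class's map assigns a feature the number of fold-sets containing
   it divided by the total number of selections for that class, so maps
   sum to one. The denominator is the realized selection count, not
   K·k·iterations — sets can be short near termination. Group maps are
   entrywise means over replicate ("subject") maps. Difference maps for
   grid-shaped features are smoothed with an isotropic unit-variance
   Gaussian truncated at 3σ.

4. **Permutation thresholds** (`permutation`). Per permutation, every
   replicate's labels are independently shuffled (class counts
   preserved), the full CV pipeline reruns, and all m values of the
   (group-averaged) per-class map are pooled; the (1 − α) empirical
   quantile (linear interpolation) of the pooled null is the class
   threshold, and features whose observed probability strictly exceeds
   it survive. Optional cluster-size pruning removes surviving features
   outside 8-connected (2-D) or 26-connected (3-D) components of a
   minimum size. Default n_perm = 100; the bundled analyses use a
   scaled-down 25-permutation variant (7,500 pooled values per class
   still resolve the 99.9th percentile).

   **Matched iteration budgets.** Null searches do not use the accuracy
   criterion: each permutation's fold runs exactly as many elimination
   iterations as the corresponding observed fold. On permuted labels
   the remaining-feature decoding accuracy sits at or below chance from
   the first iteration (the remaining features are precisely those the
   sparse fit declined to use), so criterion-terminated null searches
   stop almost immediately, producing null maps ~10× more concentrated
   than the observed map and thresholds above every observed value. A
   pooled-value comparison is only meaningful between maps that
   distribute probability over comparable selection counts; matching
   the budgets achieves that and reproduces the equal observed/null
   per-permutation cost evident in the reference analyses. The
   criterion-terminated variant remains available (`observed=None`).

5. **Evaluation** (`evaluation`). Localization accuracy against a
   planted support counts false positives and false negatives equally:
   `(1 − |predicted Δ truth| / m) · 100`, per pattern (the other
   pattern's features count as negatives). ROC curves score features by
   probability-map value (pipeline) or |weight| / |correlation| with
   sign-based class assignment (one-shot baselines). Independent-test
   accuracy trains a linear SVM on training rows restricted to the
   localized features and reports percent correct on unseen rows.

## Synthetic data

`synth_data` emulates the standard two-pattern toy benchmark: binary
patterns u1, u2 with disjoint supports (25 features each by default,
either fixed first/last blocks or random placement), data
`A = P + c·N` with 10 rows of u1 then 10 rows of u2 (t = 20, m = 300),
and colored Gaussian noise: white noise passed through an AR(1) filter
(coefficient 0.3) down each column, then standardized to sample mean 0
and variance 1 (ddof = 1) — "colored, unit variance" with mild serial
correlation. Replicates share the patterns and redraw the noise; test
sets use a separate substream. All randomness flows from one master
seed through named substreams (patterns / per-replicate noise / CV /
permutations / test set), so runs are bit-reproducible.

The default noise scale is c = 1 (unit-variance noise), as the
pattern-plus-noise model states. Under the implemented SNR formula —
temporal SNR per nonzero pattern column `10·log₁₀(‖p‖²/‖n‖²)`, spatial
SNR per row, both averaged — the default dataset sits at exactly
`10·log₁₀(10/19) ≈ −2.8 dB` temporal SNR (column standardization fixes
each noise column's sum of squares at t − 1). Reference analyses of
this benchmark quote considerably lower dB values for nominally the
same setup; no single power-ratio formula reconciles their temporal and
spatial figures, so those printed values are treated as labels of
convenience, not calibration targets. `noise_scale_for_tsnr()` inverts
the closed form above for SNR sweeps.

What the generator does *not* emulate: hemodynamic response shapes,
spatial autocorrelation of fMRI noise, optical-imaging baseline drift,
motion artifacts. Passing tests therefore demonstrate the machinery's
correctness and its behavior under idealized colored noise, not
performance on real acquisitions.

## Numerical choices

- LP: HiGHS with presolve off (faster at these sizes); infeasibility is
  raised as an explicit error; unboundedness cannot occur (objective
  bounded below by 0) and is asserted.
- Inner decode: the linear kernel is precomputed once per call; a
  feature matrix with no informative columns returns 50% by convention.
- Quantiles: linear interpolation between order statistics.
- Ties at a permutation threshold are excluded (strict inequality).
- Sparse searches also stop when fewer remaining columns than rows
  would make the exact regression infeasible.
- Degenerate inputs: single-class labels, empty feature sets, all-zero
  patterns, and mismatched shapes raise `ValueError` with messages.

## Problem sizes in the bundled analyses

The acceptance script and the heavier tests run the benchmark at its
native size (5 replicates × 20×300, K = 20, k = 2, α = 0.001) with the
25-permutation scaled-down null. Property tests that need many
repetitions (specificity on pure noise, SNR monotonicity, method
ordering) run at reduced feature counts (m = 60–120) chosen so each
property is still exercised well above its detection floor.

## Known limitations

- The group permutation null's upper tail is set by features that
  happen to track a permuted labeling consistently across several
  replicates at once; with few replicates this tail is heavy, and true
  features whose noise draw is unfavorable in most replicates can fall
  below the threshold (false negatives dominate; false positives are
  rare in practice).
- At t = 20 rows, outer folds share 19 of 20 rows, so per-replicate
  fold selections are strongly dependent; the probability map's
  "frequency across folds" is closer to a stability probe than an
  independent-resample estimate.
- Multiclass problems, searchlight/ROI analyses, and parametric (random
  field) or FDR corrections are out of scope.
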