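# spl-mvpa — sparse representation-based pattern localization

Two-class MVPA decoding tells you *that* two stimulus conditions or
brain states differ; pattern localization tells you *where*. Most
feature-selection pipelines stop at a small subset sufficient for
classification. This package implements the SPL (sparse pattern
localization) algorithm, whose goal is the opposite: recover **all**
features carrying class information — voxels in fMRI, pixels in optical
imaging — and split them into the two class-preferring sets.

## The algorithm

Given a data matrix `A ∈ R^{t×m}` (rows = time points/trials, columns =
features) and labels `y ∈ {+1, −1}^t`:

1. **Sparse weights.** Solve the basis-pursuit regression
   `min ‖w‖₁ s.t. A w = y` as a linear program (`w = u − v`, `u, v ≥ 0`).
   The optimum has at most `t` nonzeros; the *sign* of a weight encodes
   which class the feature's activity follows.
2. **Recursive elimination (per outer CV fold).** Remove the `k` most
   positive and `k` most negative features, re-fit on the remainder,
   and repeat until a linear-SVM inner cross-validation on the
   remaining features decodes at chance (50%). The union of removals,
   split by sign, approximates *all* informative features: correlated
   informative features that sparse regression initially ignores
   surface after their proxies are removed.
3. **Probability maps.** Across the `K` outer folds, each class's map is
   the per-feature selection frequency (appearances ÷ total selections;
   maps sum to 1). Replicate ("subject") maps are averaged for group
   analyses.
4. **Permutation test.** Rerun the whole pipeline under random label
   permutations (each null fold matched to the observed fold's
   iteration budget), pool all map values into one null distribution
   per class, threshold the observed maps at the empirical `1 − α`
   percentile, optionally prune small clusters. What survives are the
   two localized patterns.

A linear-SVM weight variant and a univariate-correlation baseline are
included, plus a synthetic benchmark generator (planted binary patterns
in colored Gaussian noise), evaluation against planted truth
(localization accuracy, ROC/AUC, independent-test decoding), and an
optional NIfTI adapter for masked 4-D volumes.

## Worked example

```python
import numpy as np, spl

# 3 replicates of a 20x60 dataset: two planted 6-feature patterns
spec = spl.SimulationSpec(m=60, support_size=6, n_replicates=3,
                          noise_scale=0.5, seed=42)
patterns, datasets = spl.make_replicates(spec)
print("planted supports:", patterns.support1.tolist(), patterns.support2.tolist())

res = spl.localize_study(datasets, K=10, k=2, alpha=0.01, n_perm=20,
                         level="group", seed=42)
print("pattern 1 features:", res.patterns.class_pos_features.tolist())
print("pattern 2 features:", res.patterns.class_neg_features.tolist())

s1 = spl.localization_accuracy(res.patterns.class_pos_features,
                               patterns.support1, spec.m)
s2 = spl.localization_accuracy(res.patterns.class_neg_features,
                               patterns.support2, spec.m)
print(f"localization accuracy: {s1.accuracy_pct:.1f}% / {s2.accuracy_pct:.1f}%")
```

prints

```
planted supports: [14, 24, 31, 39, 46, 59] [3, 5, 12, 18, 36, 48]
pattern 1 features: [14, 24, 31, 39, 46, 59]
pattern 2 features: [5, 12, 36, 48]
localization accuracy: 100.0% / 96.7%
```

The first planted pattern is recovered exactly; the second misses two
features (18 and 3) whose noise draws were unfavorable in most
replicates, costing 2/60 = 3.3 accuracy points. No noise feature
survives the permutation threshold.

The same analysis from the shell:

```sh
spl simulate --spec spec.yaml --out data/
spl run --matrix data/replicate_00.tsv --labels data/labels_00.tsv \
        --folds 10 --k 2 --out result/
spl permtest --inputs data/replicate_00.tsv --inputs data/replicate_01.tsv \
             --labels data/labels_00.tsv --labels data/labels_01.tsv \
             --level group --alpha 0.01 --n-perm 20 --out perm/
spl evaluate --result perm/ --truth data/truth.json
```

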