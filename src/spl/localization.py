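"""Outer cross-validation and probability-map construction.

The dataset rows are partitioned into K non-overlapping folds; the
recursive search runs on each fold's training rows, yielding K pairs of
selected feature sets.  A class's probability map assigns each feature
the number of fold-sets containing it divided by the total number of
selections for that class, i.e. a selection-frequency distribution over
features that sums to one.  Frequently reselected features are the
candidates for the class's pattern; one-off selections are mostly noise
and are later rejected by the permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from ._rng import spawn_seed
from .recursive_search import CHANCE_PCT, DEFAULT_INNER_FOLDS, FoldSelection, recursive_search
from .synth_data import LabeledDataset

__all__ = [
    "ProbabilityMap",
    "CVResult",
    "fold_indices",
    "run_cv",
    "probability_map",
    "average_maps",
    "difference_map",
]


@dataclass
class ProbabilityMap:
    """Per-feature selection frequencies for one class; entries sum to 1."""

    p: np.ndarray
    class_label: int
    n_folds: int

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0):
            raise ValueError("probabilities must be nonnegative")
        if self.class_label not in (+1, -1):
            raise ValueError("class_label must be +1 or -1")


@dataclass
class CVResult:
    folds: list[FoldSelection]
    map_pos: ProbabilityMap
    map_neg: ProbabilityMap


def fold_indices(t: int, K: int) -> list[np.ndarray]:
    """Contiguous row partition into K folds; first ``t mod K`` folds get one extra row."""
    if K > t:
        raise ValueError(f"K={K} exceeds row count {t}")
    sizes = np.full(K, t // K)
    sizes[: t % K] += 1
    edges = np.r_[0, np.cumsum(sizes)]
    return [np.arange(edges[i], edges[i + 1]) for i in range(K)]


def run_cv(
    dataset: LabeledDataset,
    K: int,
    k: int,
    threshold: float = CHANCE_PCT,
    seed: int = 0,
    method: str = "sparse_lp",
    inner_folds: int = DEFAULT_INNER_FOLDS,
    max_iter: int | None = None,
    iteration_schedule: Sequence[int] | None = None,
) -> CVResult:
    """K-fold outer cross-validation of the recursive feature search.

    In fold i the i-th part of the rows is held out and the search runs
    on the remaining rows only; the held-out rows are never touched.
    ``iteration_schedule`` (one entry per fold) switches each fold's
    search to a fixed iteration budget — used by the permutation test
    to mirror an observed run's selection counts.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if iteration_schedule is not None and len(iteration_schedule) != K:
        raise ValueError("iteration_schedule must have one entry per fold")
    folds = []
    for i, held_out in enumerate(fold_indices(dataset.n_rows, K)):
        train = np.setdiff1d(np.arange(dataset.n_rows), held_out)
        folds.append(
            recursive_search(
                dataset.A[train],
                dataset.y[train],
                k=k,
                threshold=threshold,
                max_iter=max_iter,
                seed=spawn_seed(seed, "fold", i),
                method=method,
                inner_folds=inner_folds,
                n_iterations=None if iteration_schedule is None else int(iteration_schedule[i]),
            )
        )
    m = dataset.n_features
    map_pos = probability_map([f.pos_features for f in folds], m, class_label=+1)
    map_neg = probability_map([f.neg_features for f in folds], m, class_label=-1)
    return CVResult(folds=folds, map_pos=map_pos, map_neg=map_neg)


def probability_map(
    selections: Sequence[Sequence[int]], m: int, class_label: int = +1
) -> ProbabilityMap:
    """Selection-frequency map: appearances of each feature across the
    fold sets divided by the total number of selected features."""
    counts = np.zeros(m)
    total = 0
    for sel in selections:
        uniq = np.unique(np.asarray(sel, dtype=int))
        if uniq.size and (uniq.min() < 0 or uniq.max() >= m):
            raise ValueError("feature index out of range")
        counts[uniq] += 1
        total += uniq.size
    if total == 0:
        warnings.warn("no features selected in any fold; probability map is all zero")
        p = counts
    else:
        p = counts / total
    return ProbabilityMap(p=p, class_label=class_label, n_folds=len(selections))


def average_maps(maps: Sequence[ProbabilityMap]) -> ProbabilityMap:
    """Entrywise mean of per-replicate maps of the same class (group map)."""
    if not maps:
        raise ValueError("no maps to average")
    if len({mp.class_label for mp in maps}) > 1:
        raise ValueError("cannot average maps of different classes")
    if len({mp.p.shape[0] for mp in maps}) > 1:
        raise ValueError("maps have different feature counts")
    return ProbabilityMap(
        p=np.mean([mp.p for mp in maps], axis=0),
        class_label=maps[0].class_label,
        n_folds=maps[0].n_folds,
    )


def difference_map(
    map_a: ProbabilityMap,
    map_b: ProbabilityMap,
    grid: tuple[int, ...],
    sigma: float = 1.0,
) -> np.ndarray:
    """(p_a - p_b) on the feature grid, smoothed with an isotropic Gaussian.

    The kernel has zero mean and variance ``sigma**2`` per axis (default
    unit variance, truncated at 3 sigma); positive regions favor class a,
    negative regions class b.
    """
    if map_a.p.shape != map_b.p.shape:
        raise ValueError("maps have different feature counts")
    if int(np.prod(grid)) != map_a.p.shape[0]:
        raise ValueError(f"grid {grid} does not match {map_a.p.shape[0]} features")
    img = (map_a.p - map_b.p).reshape(grid)
    return gaussian_filter(img, sigma=sigma, truncate=3.0, mode="constant")
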