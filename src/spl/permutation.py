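"""Permutation-test thresholding of probability maps.

Under the null hypothesis of no feature/label association, relabeling
the rows at random and rerunning the whole pipeline produces maps whose
values reflect chance selection frequencies.  Pooling all feature values
from every permutation map yields one null distribution per class; the
(1 - alpha) empirical percentile of that pool is the class threshold,
and the features whose observed probability strictly exceeds it form
the localized pattern.  At the group level the relabeling is applied to
every replicate independently and the per-permutation maps are averaged
across replicates before pooling, mirroring how the observed group map
is built.  An optional cluster-size criterion on a feature grid removes
isolated supra-threshold features (8-connectivity in 2-D,
26-connectivity in 3-D).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from ._rng import spawn_seed, substream
from .localization import ProbabilityMap, average_maps, run_cv
from .recursive_search import CHANCE_PCT, DEFAULT_INNER_FOLDS
from .synth_data import LabeledDataset

__all__ = [
    "NullDistribution",
    "LocalizedPatterns",
    "SPLResult",
    "permute_labels",
    "build_null",
    "threshold_at",
    "localize",
    "localize_study",
]

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 100


@dataclass
class NullDistribution:
    values: np.ndarray
    class_label: int
    n_permutations: int
    level: Literal["individual", "group"]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if np.any(self.values < 0):
            raise ValueError("null values must be nonnegative")


@dataclass
class LocalizedPatterns:
    """The final thresholded feature sets for the two classes."""

    class_pos_features: np.ndarray
    class_neg_features: np.ndarray
    thresholds: tuple[float, float]
    alpha: float
    cluster_min: int = 1


@dataclass
class SPLResult:
    """Everything the full pipeline produces for one study."""

    cv_results: list  # one CVResult per dataset
    map_pos: ProbabilityMap
    map_neg: ProbabilityMap
    null_pos: "NullDistribution"
    null_neg: "NullDistribution"
    patterns: "LocalizedPatterns"


def permute_labels(dataset: LabeledDataset, rng_or_seed) -> LabeledDataset:
    """Uniformly random permutation of the label vector; data untouched."""
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) else np.random.default_rng(rng_or_seed)
    return LabeledDataset(
        A=dataset.A,
        y=rng.permutation(dataset.y),
        feature_shape=dataset.feature_shape,
        feature_names=dataset.feature_names,
    )


def build_null(
    datasets: Sequence[LabeledDataset],
    K: int,
    k: int,
    n_perm: int = DEFAULT_N_PERM,
    level: Literal["individual", "group"] = "group",
    seed: int = 0,
    threshold: float = CHANCE_PCT,
    method: str = "sparse_lp",
    inner_folds: int = DEFAULT_INNER_FOLDS,
    observed=None,
) -> tuple[NullDistribution, NullDistribution]:
    """Pooled null distributions of probability values, one per class.

    Each permutation relabels every dataset (independent substreams),
    reruns the full cross-validated recursive search, and contributes
    all m values of the resulting (group-averaged) map to the pool, so
    each null holds ``n_perm * m`` samples.

    ``observed`` (the list of :class:`~spl.localization.CVResult` from
    the un-permuted analysis, one per dataset) makes every null search
    run the same per-fold iteration budget as the observed run.  This
    is the recommended mode: a null map is only comparable to the
    observed map when both distribute probability over a similar number
    of selections — criterion-terminated null searches stop almost
    immediately (permuted labels decode at or below chance from the
    first iteration), concentrating the null maps and inflating the
    thresholds.  With ``observed=None`` each null search terminates by
    the accuracy criterion like the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if level == "group" and len(datasets) < 2:
        raise ValueError("group-level test needs at least 2 datasets")
    if level == "individual" and len(datasets) != 1:
        raise ValueError("individual-level test takes exactly 1 dataset")
    if observed is not None and len(observed) != len(datasets):
        raise ValueError("need one observed CVResult per dataset")
    schedules = (
        None
        if observed is None
        else [[f.n_iterations for f in res.folds] for res in observed]
    )
    pools: dict[int, list[np.ndarray]] = {+1: [], -1: []}
    for p in range(n_perm):
        maps = {+1: [], -1: []}
        for j, ds in enumerate(datasets):
            perm = permute_labels(ds, substream(seed, "perm-labels", p, j))
            try:
                res = run_cv(
                    perm, K=K, k=k, threshold=threshold,
                    seed=spawn_seed(seed, "perm-cv", p, j),
                    method=method, inner_folds=inner_folds,
                    iteration_schedule=None if schedules is None else schedules[j],
                )
            except Exception as exc:
                raise RuntimeError(f"permutation {p}, dataset {j} failed") from exc
            maps[+1].append(res.map_pos)
            maps[-1].append(res.map_neg)
        for cls in (+1, -1):
            pools[cls].append(average_maps(maps[cls]).p)
        logger.debug("permutation %d/%d done", p + 1, n_perm)
    return tuple(
        NullDistribution(
            values=np.concatenate(pools[cls]),
            class_label=cls,
            n_permutations=n_perm,
            level=level,
        )
        for cls in (+1, -1)
    )


def threshold_at(null: NullDistribution, alpha: float) -> float:
    """Empirical (1 - alpha) quantile of the pooled null (linear interpolation)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if null.values.size == 0:
        raise ValueError("empty null distribution")
    return float(np.quantile(null.values, 1 - alpha))


def _prune_clusters(mask: np.ndarray, grid: tuple[int, ...], cluster_min: int) -> np.ndarray:
    img = mask.reshape(grid)
    structure = np.ones((3,) * img.ndim, dtype=bool)  # 8-/26-connectivity
    labels, n = ndimage.label(img, structure=structure)
    keep = np.zeros_like(img, dtype=bool)
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() >= cluster_min:
            keep |= comp
    return keep.ravel()


def localize(
    map_pos: ProbabilityMap,
    map_neg: ProbabilityMap,
    T1: float,
    T2: float,
    alpha: float,
    cluster_min: int = 1,
    grid: tuple[int, ...] | None = None,
) -> LocalizedPatterns:
    """Apply the class thresholds (strict inequality) and optional
    cluster-size pruning to obtain the two localized feature sets."""
    if cluster_min > 1 and grid is None:
        raise ValueError("cluster_min > 1 requires a feature grid")
    masks = {}
    for cls, (mp, T) in {+1: (map_pos, T1), -1: (map_neg, T2)}.items():
        mask = mp.p > T
        if cluster_min > 1:
            mask &= _prune_clusters(mask, grid, cluster_min)
        masks[cls] = np.flatnonzero(mask)
    return LocalizedPatterns(
        class_pos_features=masks[+1],
        class_neg_features=masks[-1],
        thresholds=(float(T1), float(T2)),
        alpha=alpha,
        cluster_min=cluster_min,
    )


def localize_study(
    datasets: Sequence[LabeledDataset],
    K: int,
    k: int,
    alpha: float,
    n_perm: int = DEFAULT_N_PERM,
    level: Literal["individual", "group"] = "group",
    seed: int = 0,
    method: str = "sparse_lp",
    threshold: float = CHANCE_PCT,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    cluster_min: int = 1,
    grid: tuple[int, ...] | None = None,
) -> SPLResult:
    """The full pipeline on one study: observed cross-validated searches,
    (group-)averaged probability maps, matched-budget permutation nulls,
    thresholds, and the two localized patterns."""
    cv_results = [
        run_cv(ds, K=K, k=k, threshold=threshold, seed=spawn_seed(seed, "cv", j),
               method=method, inner_folds=inner_folds)
        for j, ds in enumerate(datasets)
    ]
    map_pos = average_maps([r.map_pos for r in cv_results])
    map_neg = average_maps([r.map_neg for r in cv_results])
    null_pos, null_neg = build_null(
        datasets, K=K, k=k, n_perm=n_perm, level=level, seed=seed,
        threshold=threshold, method=method, inner_folds=inner_folds,
        observed=cv_results,
    )
    patterns = localize(
        map_pos, map_neg,
        threshold_at(null_pos, alpha), threshold_at(null_neg, alpha),
        alpha=alpha, cluster_min=cluster_min, grid=grid,
    )
    return SPLResult(
        cv_results=cv_results, map_pos=map_pos, map_neg=map_neg,
        null_pos=null_pos, null_neg=null_neg, patterns=patterns,
    )
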