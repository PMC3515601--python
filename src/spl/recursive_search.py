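"""Recursive feature elimination within one cross-validation fold.

Each iteration: fit signed weights on the remaining features, remove the
k most positive and k most negative features (recording them in the
class +1 and class -1 sets respectively), then measure decoding accuracy
of a linear SVM on what is left via an inner stratified cross-validation.
The loop ends the first time accuracy falls to the chance threshold, so
the union of removed features over iterations aims to capture *all*
informative features rather than a minimal discriminative subset:
features correlated with an already-removed feature receive weight only
after its removal, surfacing in later iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from ._rng import spawn_seed
from .sparse_weights import WeightVector, weight_function

__all__ = ["FoldSelection", "select_top_k", "decode_accuracy", "recursive_search"]

logger = logging.getLogger(__name__)

CHANCE_PCT = 50.0
DEFAULT_INNER_FOLDS = 20


@dataclass
class FoldSelection:
    """Outcome of the recursive search in one outer fold."""

    pos_features: list[int] = field(default_factory=list)
    neg_features: list[int] = field(default_factory=list)
    n_iterations: int = 0
    accuracy_trace: list[float] = field(default_factory=list)


def select_top_k(w: WeightVector | np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the k largest positive and k smallest negative weights.

    Zero weights are never selected; fewer than k are returned when
    fewer strictly signed weights exist.  Output is ordered by
    decreasing |weight|.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    w = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    pos = np.flatnonzero(w > 0)
    neg = np.flatnonzero(w < 0)
    pos = pos[np.argsort(-w[pos], kind="stable")][:k]
    neg = neg[np.argsort(w[neg], kind="stable")][:k]
    return pos, neg


def decode_accuracy(
    A: np.ndarray,
    y: np.ndarray,
    n_folds: int = DEFAULT_INNER_FOLDS,
    seed: int = 0,
) -> float:
    """Mean linear-SVM label-prediction accuracy (%) over stratified CV.

    A feature matrix carrying no information — zero columns, or no
    columns at all — returns the two-class chance level 50% by
    convention.  Folds are capped at the row count (so 20 folds on 19
    rows is leave-one-out); splits are stratified when the fold count
    permits, plain otherwise.  A training split that loses a class
    entirely contributes chance predictions for its test rows.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("decoding needs both classes present")
    if A.shape[1] == 0 or not np.any(A.std(axis=0) > 0):
        return CHANCE_PCT
    n_splits = min(n_folds, y.shape[0])
    if n_splits < 2:
        raise ValueError("need at least 2 rows for inner cross-validation")
    if n_splits <= counts.min():
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    else:
        cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    G = A @ A.T  # one Gram matrix serves every fold of the linear SVM
    correct = 0.0
    for tr, te in cv.split(A, y):
        if len(np.unique(y[tr])) < 2:
            correct += 0.5 * te.size
            continue
        clf = SVC(kernel="precomputed", C=1.0).fit(G[np.ix_(tr, tr)], y[tr])
        correct += float(np.sum(clf.predict(G[np.ix_(te, tr)]) == y[te]))
    return 100.0 * correct / y.shape[0]


def recursive_search(
    A: np.ndarray,
    y: np.ndarray,
    k: int,
    threshold: float = CHANCE_PCT,
    max_iter: int | None = None,
    seed: int = 0,
    method: str = "sparse_lp",
    inner_folds: int = DEFAULT_INNER_FOLDS,
    n_iterations: int | None = None,
) -> FoldSelection:
    """Iterate weight fit -> top-k removal -> decode until chance accuracy.

    Feature indices in the result refer to the original columns of
    ``A``.  Termination: accuracy <= ``threshold`` (evaluated after
    removal; the terminating iteration's selections are kept), the
    feature pool exhausted (nothing selectable, or for the exact-
    regression weights fewer remaining columns than rows), or
    ``max_iter`` (default ``floor(m / 2k)``) reached.

    When ``n_iterations`` is given the search instead runs exactly that
    many iterations (pool permitting) and skips the decoding step
    entirely, leaving an empty accuracy trace.  This fixed-budget mode
    is used by the permutation test so that null runs select as many
    features as the observed run they are compared against.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    t, m = A.shape
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    if k >= t / 2:
        raise ValueError(f"k={k} must be below half the row count {t}")
    if max_iter is None:
        max_iter = max(1, m // (2 * k))
    if n_iterations is not None:
        max_iter = n_iterations
    fit = weight_function(method)

    remaining = np.arange(m)
    out = FoldSelection()
    decode_seed = spawn_seed(seed, "decode")
    while out.n_iterations < max_iter:
        if method == "sparse_lp" and remaining.size < t:
            logger.info("feature pool below row count; stopping search")
            break
        wv = fit(A[:, remaining], y)
        pos, neg = select_top_k(wv, k)
        if pos.size == 0 and neg.size == 0:
            logger.info("no signed weights left to select; stopping search")
            break
        out.pos_features.extend(int(i) for i in remaining[pos])
        out.neg_features.extend(int(i) for i in remaining[neg])
        remaining = np.delete(remaining, np.concatenate([pos, neg]))
        out.n_iterations += 1
        if n_iterations is not None:
            continue
        acc = decode_accuracy(A[:, remaining], y, n_folds=inner_folds, seed=decode_seed)
        out.accuracy_trace.append(acc)
        logger.info("iteration %d: removed %d+%d features, accuracy %.1f%%",
                    out.n_iterations, pos.size, neg.size, acc)
        if acc <= threshold:
            break
    return out
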