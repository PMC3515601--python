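"""Scoring localized patterns against planted ground truth.

Localization accuracy counts every wrongly classified feature — false
positives and false negatives alike — so a predicted set is scored as
``(1 - |predicted symmetric-difference truth| / m) * 100``.  ROC curves
sweep a threshold over per-feature scores (probability-map values for
the pipeline, |weight| or |correlation| for the single-shot baselines)
against the planted support.  Independent-test accuracy trains a linear
SVM on the training rows restricted to the localized features and
reports percent correct on unseen test rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc, roc_curve
from sklearn.svm import SVC

from .localization import ProbabilityMap
from .sparse_weights import WeightVector
from .synth_data import LabeledDataset

__all__ = [
    "LocalizationScore",
    "RocCurve",
    "localization_accuracy",
    "roc_from_map",
    "independent_test_accuracy",
]


@dataclass
class LocalizationScore:
    accuracy_pct: float
    n_wrong: int
    false_positives: np.ndarray
    false_negatives: np.ndarray


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    method_label: str = ""


def localization_accuracy(predicted, truth, m: int) -> LocalizationScore:
    """Fraction of the m features classified correctly, as a percentage."""
    predicted = np.unique(np.asarray(predicted, dtype=int))
    truth = np.unique(np.asarray(truth, dtype=int))
    for idx in (predicted, truth):
        if idx.size and (idx.min() < 0 or idx.max() >= m):
            raise ValueError("feature index out of range")
    fp = np.setdiff1d(predicted, truth)
    fn = np.setdiff1d(truth, predicted)
    n_wrong = fp.size + fn.size
    return LocalizationScore(
        accuracy_pct=(1 - n_wrong / m) * 100.0,
        n_wrong=int(n_wrong),
        false_positives=fp,
        false_negatives=fn,
    )


def roc_from_map(scores, truth, method_label: str = "") -> RocCurve:
    """ROC of per-feature scores against the planted support.

    ``scores`` may be a :class:`ProbabilityMap`, a
    :class:`WeightVector` (its magnitudes are used), or a plain vector.
    """
    if isinstance(scores, ProbabilityMap):
        s = scores.p
    elif isinstance(scores, WeightVector):
        s = np.abs(scores.w)
    else:
        s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    truth = np.unique(np.asarray(truth, dtype=int))
    if truth.size == 0 or truth.size == s.shape[0]:
        raise ValueError("truth set must be nonempty and not cover all features")
    labels = np.zeros(s.shape[0], dtype=int)
    labels[truth] = 1
    fpr, tpr, _ = roc_curve(labels, s)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(auc(fpr, tpr)), method_label=method_label)


def independent_test_accuracy(
    train: LabeledDataset,
    test: LabeledDataset,
    features,
) -> float:
    """Percent correct of a linear SVM trained on the selected features only."""
    features = np.unique(np.asarray(features, dtype=int))
    if features.size == 0:
        raise ValueError("empty feature set")
    if train.n_features != test.n_features:
        raise ValueError("train and test sets have different feature spaces")
    clf = SVC(kernel="linear", C=1.0).fit(train.A[:, features], train.y)
    return 100.0 * float(np.mean(clf.predict(test.A[:, features]) == test.y))
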