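"""Per-feature weight determination.

The primary method is minimum-L1-norm regression (basis pursuit):

    min ||w||_1   subject to   A w = y,

solved as a linear program by the substitution ``w = u - v`` with
``u, v >= 0``, giving ``min 1'(u+v)`` s.t. ``[A, -A][u; v] = y``.  For an
underdetermined system (t <= m) the optimal ``w`` is sparse — generically
at most ``t`` nonzeros — and the sign of each nonzero weight indicates
which class the feature's activity favors.  A linear soft-margin SVM and
univariate Pearson correlation provide the dense comparison weightings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import linprog
from sklearn.svm import SVC

__all__ = [
    "WeightVector",
    "InfeasibleSystemError",
    "solve_l1",
    "svm_weights",
    "correlation_weights",
    "weight_function",
]

#: relative magnitude below which an LP weight counts as zero
NONZERO_RTOL = 1e-8


class InfeasibleSystemError(RuntimeError):
    """Raised when ``A w = y`` has no solution."""


@dataclass
class WeightVector:
    w: np.ndarray
    method: Literal["sparse_lp", "svm", "correlation"]
    solver_status: str = "ok"

    def nonzero(self, rtol: float = NONZERO_RTOL) -> np.ndarray:
        """Indices with |w| above ``rtol * max|w|``."""
        scale = np.max(np.abs(self.w)) if self.w.size else 0.0
        if scale == 0:
            return np.array([], dtype=int)
        return np.flatnonzero(np.abs(self.w) > rtol * scale)


def solve_l1(A: np.ndarray, y: np.ndarray) -> WeightVector:
    """Minimum-L1-norm solution of the equality-constrained regression.

    Raises :class:`InfeasibleSystemError` when no exact solution exists
    (e.g. more independent equations than free features).
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    t, m = A.shape
    if y.shape[0] != t:
        raise ValueError("A and y have incompatible shapes")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input")
    res = linprog(
        c=np.ones(2 * m),
        A_eq=np.hstack([A, -A]),
        b_eq=y,
        bounds=(0, None),
        method="highs",
        # presolve spends more than it saves on these small dense systems
        options={"presolve": False},
    )
    if res.status == 2:
        raise InfeasibleSystemError(f"A w = y infeasible: {res.message}")
    # the objective 1'(u+v) is bounded below by 0: unboundedness cannot occur
    assert res.status == 0, f"unexpected LP status {res.status}: {res.message}"
    w = res.x[:m] - res.x[m:]
    resid = float(np.max(np.abs(A @ w - y))) if t else 0.0
    return WeightVector(w=w, method="sparse_lp", solver_status=f"optimal, residual={resid:.2e}")


def svm_weights(A: np.ndarray, y: np.ndarray, C: float = 1.0) -> WeightVector:
    """Primal weight vector of a linear soft-margin SVM (hinge loss, fixed C)."""
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("SVM weights need both classes present")
    clf = SVC(kernel="linear", C=C).fit(A, y)
    # sklearn orders classes ascending, so decision > 0 <=> larger label:
    # coef_ already points toward the +1 class
    return WeightVector(w=clf.coef_.ravel().copy(), method="svm")


def correlation_weights(A: np.ndarray, y: np.ndarray) -> WeightVector:
    """Pearson correlation of each feature column with the label vector."""
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Ac = A - A.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(Ac**2, axis=0))
    sy = np.sqrt(np.sum(yc**2))
    const = sx == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant feature column(s) assigned weight 0")
        sx = np.where(const, 1.0, sx)
    w = (Ac.T @ yc) / (sx * sy)
    w[const] = 0.0
    return WeightVector(w=w, method="correlation")


def weight_function(method: str):
    """Resolve a method name to its weight-determination callable."""
    table = {"sparse_lp": solve_l1, "svm": svm_weights, "correlation": correlation_weights}
    try:
        return table[method]
    except KeyError:
        raise ValueError(f"unknown weight method {method!r}; choose from {sorted(table)}")
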