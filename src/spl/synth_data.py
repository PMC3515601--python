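"""Synthetic two-class pattern-plus-noise datasets.

The generator emulates the standard toy model for pattern-localization
benchmarks: each row of the data matrix is one of two binary spatial
patterns ``u1``/``u2`` (disjoint supports) corrupted by additive colored
Gaussian noise,

    A = P + c * N,    y_i = +1 for u1 rows, -1 for u2 rows,

where ``P`` stacks ``rows_per_class`` copies of each pattern, ``N`` has
temporally correlated (AR(1)) unit-variance Gaussian columns, and the
scalar ``c`` (``noise_scale``) drives the signal-to-noise ratio.
Replicates ("subjects") share the patterns but redraw the noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._rng import substream

__all__ = [
    "noise_scale_for_tsnr",
    "SimulationSpec",
    "PatternPair",
    "LabeledDataset",
    "make_pattern_pair",
    "make_colored_noise",
    "make_dataset",
    "make_test_set",
    "make_replicates",
    "compute_snr",
]

#: AR(1) coefficient of the temporal coloring filter.
AR1_COEF = 0.3


def noise_scale_for_tsnr(tsnr_db: float, rows_per_class: int = 10) -> float:
    """Noise scale c that puts the default dataset at a target temporal SNR.

    Column standardization fixes each noise column's sum of squares at
    exactly t - 1 (t = 2 * rows_per_class), and a binary pattern column
    has sum of squares rows_per_class, so

        tSNR(c) = 10 log10( rows_per_class / ((t - 1) c^2) )

    holds deterministically and can be inverted for c.
    """
    t = 2 * rows_per_class
    return float(np.sqrt(rows_per_class / ((t - 1) * 10 ** (tsnr_db / 10))))


#: Default noise scale: unit-variance noise, as the pattern-plus-noise
#: model states.  The default 20x300 dataset then sits at -2.8 dB
#: temporal SNR; use :func:`noise_scale_for_tsnr` to target other
#: operating points for SNR sweeps.
DEFAULT_NOISE_SCALE = 1.0


@dataclass(frozen=True)
class SimulationSpec:
    """Configuration of one simulated study.

    Defaults reproduce the small-sample benchmark: 5 replicates of a
    20x300 matrix (10 rows per class), two disjoint 25-feature binary
    patterns, unit-scale colored noise.
    """

    m: int = 300
    rows_per_class: int = 10
    n_replicates: int = 5
    noise_scale: float = DEFAULT_NOISE_SCALE
    support_size: int = 25
    support_mode: Literal["fixed", "random"] = "random"
    seed: int = 0

    def __post_init__(self):
        if self.m < 2 * self.support_size:
            raise ValueError(
                f"m={self.m} cannot host two disjoint supports of size {self.support_size}"
            )
        if self.rows_per_class < 1:
            raise ValueError("rows_per_class must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")


@dataclass(frozen=True)
class PatternPair:
    """Two binary patterns with disjoint supports."""

    u1: np.ndarray
    u2: np.ndarray

    @property
    def support1(self) -> np.ndarray:
        return np.flatnonzero(self.u1)

    @property
    def support2(self) -> np.ndarray:
        return np.flatnonzero(self.u2)

    def __post_init__(self):
        if self.u1.shape != self.u2.shape:
            raise ValueError("patterns must share a feature space")
        if np.intersect1d(self.support1, self.support2).size:
            raise ValueError("pattern supports must be disjoint")


@dataclass
class LabeledDataset:
    """A data matrix ``A`` (rows = trials/time points) with +-1 labels ``y``."""

    A: np.ndarray
    y: np.ndarray
    feature_shape: tuple[int, ...] | None = None
    feature_names: list[str] | None = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.A.ndim != 2:
            raise ValueError("A must be a 2-D matrix")
        if self.A.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"row count {self.A.shape[0]} != label count {self.y.shape[0]}"
            )
        if not np.all(np.isfinite(self.A)):
            raise ValueError("A contains non-finite entries")
        if set(np.unique(self.y)) - {1.0, -1.0}:
            raise ValueError("labels must be +1/-1")
        if len(set(np.unique(self.y))) < 2:
            raise ValueError("both classes must be present")

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    @property
    def n_features(self) -> int:
        return self.A.shape[1]


def make_pattern_pair(spec: SimulationSpec) -> PatternPair:
    """Place the two binary patterns.

    ``fixed`` puts ``u1`` on the first and ``u2`` on the last
    ``support_size`` features; ``random`` draws two disjoint supports
    uniformly without replacement.
    """
    s = spec.support_size
    if spec.support_mode == "fixed":
        idx1 = np.arange(s)
        idx2 = np.arange(spec.m - s, spec.m)
    elif spec.support_mode == "random":
        rng = substream(spec.seed, "patterns")
        both = rng.choice(spec.m, size=2 * s, replace=False)
        idx1, idx2 = np.sort(both[:s]), np.sort(both[s:])
    else:
        raise ValueError(f"unknown support_mode {spec.support_mode!r}")
    u1 = np.zeros(spec.m)
    u2 = np.zeros(spec.m)
    u1[idx1] = 1.0
    u2[idx2] = 1.0
    return PatternPair(u1=u1, u2=u2)


def make_colored_noise(t: int, m: int, seed_or_rng) -> np.ndarray:
    """A ``t x m`` matrix of temporally correlated Gaussian noise.

    Each column is white Gaussian noise passed through an AR(1) filter
    (coefficient 0.3) down the rows and then standardized to sample
    mean 0 and sample variance 1 (ddof=1), so the marginal scale is
    fixed while mild serial correlation remains.
    """
    if t < 1 or m < 1:
        raise ValueError("t and m must be >= 1")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    e = rng.standard_normal((t, m))
    n = np.empty_like(e)
    n[0] = e[0]
    for i in range(1, t):
        n[i] = AR1_COEF * n[i - 1] + e[i]
    if t == 1:
        return np.zeros((t, m))
    n -= n.mean(axis=0)
    sd = n.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return n / sd


def _pattern_matrix(patterns: PatternPair, y: np.ndarray) -> np.ndarray:
    P = np.empty((y.shape[0], patterns.u1.shape[0]))
    P[y > 0] = patterns.u1
    P[y < 0] = patterns.u2
    return P


def make_dataset(
    patterns: PatternPair,
    spec: SimulationSpec,
    rng=None,
) -> LabeledDataset:
    """One replicate: ``rows_per_class`` u1-rows then u2-rows plus scaled noise."""
    if rng is None:
        rng = substream(spec.seed, "noise")
    y = np.r_[np.ones(spec.rows_per_class), -np.ones(spec.rows_per_class)]
    P = _pattern_matrix(patterns, y)
    N = make_colored_noise(y.shape[0], spec.m, rng)
    return LabeledDataset(A=P + spec.noise_scale * N, y=y)


def make_replicates(spec: SimulationSpec) -> tuple[PatternPair, list[LabeledDataset]]:
    """The full study: shared patterns, ``n_replicates`` independent noise draws."""
    patterns = make_pattern_pair(spec)
    datasets = [
        make_dataset(patterns, spec, rng=substream(spec.seed, "noise", r))
        for r in range(spec.n_replicates)
    ]
    return patterns, datasets


def make_test_set(
    patterns: PatternPair,
    n_per_class: int,
    noise_scale: float,
    seed: int,
) -> LabeledDataset:
    """An independent labeled test set with fresh noise (its own substream)."""
    m = patterns.u1.shape[0]
    y = np.r_[np.ones(n_per_class), -np.ones(n_per_class)]
    P = _pattern_matrix(patterns, y)
    N = make_colored_noise(y.shape[0], m, substream(seed, "test-set"))
    return LabeledDataset(A=P + noise_scale * N, y=y)


def compute_snr(dataset: LabeledDataset, patterns: PatternPair) -> tuple[float, float]:
    """Temporal and spatial SNR of a simulated dataset, in dB.

    The noise matrix is recovered as ``A - P``.  Temporal SNR is
    ``10*log10(||p_col||^2 / ||n_col||^2)`` averaged over the nonzero
    columns of the pattern matrix; spatial SNR is the same ratio per
    row, averaged over all rows.  Zero noise yields ``inf``.
    """
    P = _pattern_matrix(patterns, dataset.y)
    if not P.any():
        raise ValueError("pattern matrix is identically zero; SNR undefined")
    N = dataset.A - P
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-noise -> inf is intended
        cols = np.flatnonzero((P != 0).any(axis=0))
        tsnr = np.mean(
            10 * np.log10(np.sum(P[:, cols] ** 2, axis=0) / np.sum(N[:, cols] ** 2, axis=0))
        )
        ssnr = np.mean(10 * np.log10(np.sum(P**2, axis=1) / np.sum(N**2, axis=1)))
    return float(tsnr), float(ssnr)
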