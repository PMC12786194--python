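"""Gray-level histograms and the multilevel Otsu criterion.

Multilevel Otsu thresholding partitions the gray levels ``0..L-1`` of an
image into ``k+1`` classes by ``k`` thresholds and scores a candidate
threshold set by the between-class variance

    J(T) = sum_i  w_i * (mu_i - mu_T)**2

where ``w_i`` and ``mu_i`` are the probability mass and mean gray level of
class ``i`` under the normalized histogram and ``mu_T`` is the global mean.
Maximizing ``J`` is equivalent to minimizing the total within-class
variance, so the optimal thresholds give the best class separation the
histogram supports.

Thresholds live in the continuous box ``[1, L-1]`` (the swarm optimizers
search real vectors), but the histogram is discrete: any real threshold
between two integer bins induces the same partition, so ``J`` is evaluated
on the floors of the thresholds.  Class ``i`` covers bins
``floor(t_{i-1}) < j <= floor(t_i)``; class 1 starts at bin 0 and class
``k+1`` ends at ``L-1``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "Histogram",
    "ThresholdSet",
    "ObjectiveBreakdown",
    "compute_histogram",
    "rebin_histogram",
    "otsu_objective",
    "evaluate_thresholds",
    "brute_force_thresholds",
    "canonical_bins",
]


@dataclass(frozen=True)
class Histogram:
    """Normalized gray-level histogram.

    Parameters
    ----------
    probs : ndarray, shape (L,)
        Probability of each gray level; nonnegative, sums to 1.
    total_pixels : int
        Number of pixels the histogram was tallied from.
    """

    probs: np.ndarray
    total_pixels: int

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 1 or probs.size < 2:
            raise ValueError("histogram must be a 1-D vector with L >= 2 bins")
        if self.total_pixels < 0:
            raise ValueError("total_pixels must be nonnegative")
        if np.any(probs < 0) or not np.all(np.isfinite(probs)):
            raise ValueError("histogram probabilities must be finite and >= 0")
        if self.total_pixels > 0 and abs(float(probs.sum()) - 1.0) > 1e-9:
            raise ValueError("histogram probabilities must sum to 1")

    @property
    def n_levels(self) -> int:
        return int(self.probs.size)

    # Cumulative tables turn a k-threshold evaluation into O(k) lookups.
    @cached_property
    def _cum_p(self) -> np.ndarray:
        return np.cumsum(self.probs)

    @cached_property
    def _cum_jp(self) -> np.ndarray:
        j = np.arange(self.n_levels, dtype=float)
        return np.cumsum(j * self.probs)

    @cached_property
    def _cum_j2p(self) -> np.ndarray:
        j = np.arange(self.n_levels, dtype=float)
        return np.cumsum(j * j * self.probs)

    @cached_property
    def mean(self) -> float:
        """Global mean gray level mu_T."""
        return float(self._cum_jp[-1])

    @cached_property
    def variance(self) -> float:
        """Total gray-level variance around mu_T."""
        return float(self._cum_j2p[-1] - self.mean**2)

    def to_csv(self, path) -> None:
        """Write (bin, probability) rows for inspection."""
        import pandas as pd

        pd.DataFrame(
            {"bin": np.arange(self.n_levels), "probability": self.probs}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ThresholdSet:
    """A canonical set of real-valued thresholds in ``[1, L-1]``.

    ``values`` are sorted strictly ascending; exact duplicates are dropped
    at construction.  ``n_levels`` records the gray range the thresholds
    refer to (256 for 8-bit images).
    """

    values: np.ndarray
    n_levels: int = 256

    def __post_init__(self) -> None:
        vals = np.atleast_1d(np.asarray(self.values, dtype=float))
        if vals.size == 0:
            raise ValueError("threshold set must contain at least one value")
        if not np.all(np.isfinite(vals)):
            raise ValueError("thresholds must be finite")
        vals = np.unique(np.clip(np.sort(vals), 1.0, self.n_levels - 1))
        object.__setattr__(self, "values", vals)

    @property
    def k(self) -> int:
        return int(self.values.size)

    @property
    def floors(self) -> np.ndarray:
        """Integer bins the thresholds evaluate on."""
        return np.floor(self.values).astype(np.int64)


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """Full decomposition of the Otsu criterion at one threshold set."""

    J: float
    class_probs: np.ndarray
    class_means: np.ndarray
    global_mean: float
    within_class_variance: float
    thresholds: ThresholdSet = field(repr=False)


def compute_histogram(image: np.ndarray, n_levels: int = 256) -> Histogram:
    """Tally the normalized gray-level histogram of a 2-D intensity grid."""
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty input")
    if arr.ndim != 2:
        raise ValueError("expected a 2-D intensity grid")
    flat = arr.ravel()
    if np.any(flat < 0) or np.any(flat > n_levels - 1):
        raise ValueError("value outside gray range")
    counts = np.bincount(flat.astype(np.int64), minlength=n_levels)
    total = int(flat.size)
    return Histogram(probs=counts / total, total_pixels=total)


def rebin_histogram(hist: Histogram, n_levels: int) -> Histogram:
    """Aggregate a histogram to a coarser gray resolution.

    Bins are merged in contiguous groups of ``L // n_levels``; used to
    shrink the exhaustive-search space for oracle comparisons.
    """
    if hist.n_levels % n_levels != 0:
        raise ValueError("n_levels must divide the current bin count")
    factor = hist.n_levels // n_levels
    probs = hist.probs.reshape(n_levels, factor).sum(axis=1)
    return Histogram(probs=probs, total_pixels=hist.total_pixels)


def _class_edges(floors: np.ndarray, n_levels: int) -> np.ndarray:
    """Boundary bins [-1, f_1, ..., f_k, L-1] with coincident floors kept."""
    return np.concatenate(([-1], np.sort(floors), [n_levels - 1]))


def otsu_objective(hist: Histogram, thresholds: ThresholdSet) -> ObjectiveBreakdown:
    """Evaluate the between-class variance criterion with full breakdown.

    Classes with zero probability contribute 0 to both the between- and
    within-class terms; their means are reported as 0 to avoid 0/0.
    """
    if thresholds.n_levels != hist.n_levels:
        raise ValueError("threshold gray range does not match histogram")
    edges = _class_edges(thresholds.floors, hist.n_levels)
    P = np.concatenate(([0.0], hist._cum_p))
    M = np.concatenate(([0.0], hist._cum_jp))
    Q = np.concatenate(([0.0], hist._cum_j2p))
    lo, hi = edges[:-1] + 1, edges[1:] + 1
    w = P[hi] - P[lo]
    m1 = M[hi] - M[lo]
    m2 = Q[hi] - Q[lo]
    occupied = w > 0.0
    means = np.where(occupied, m1 / np.where(occupied, w, 1.0), 0.0)
    mu_T = hist.mean
    J = float(np.sum(w[occupied] * (means[occupied] - mu_T) ** 2))
    within = float(np.sum(m2[occupied] - w[occupied] * means[occupied] ** 2))
    return ObjectiveBreakdown(
        J=J,
        class_probs=w,
        class_means=means,
        global_mean=mu_T,
        within_class_variance=within,
        thresholds=thresholds,
    )


def evaluate_thresholds(hist: Histogram, positions: np.ndarray) -> np.ndarray:
    """Vectorized between-class variance for a batch of threshold vectors.

    Parameters
    ----------
    positions : ndarray, shape (n, k) or (k,)
        Real threshold vectors; floored, sorted and clipped internally.
        Coincident floors simply produce empty classes contributing 0.

    Returns
    -------
    ndarray, shape (n,) — J for each row (scalar input gives shape ()).
    """
    pos = np.asarray(positions, dtype=float)
    squeeze = pos.ndim == 1
    pos = np.atleast_2d(pos)
    L = hist.n_levels
    floors = np.clip(np.floor(pos).astype(np.int64), 1, L - 1)
    floors.sort(axis=1)
    n = floors.shape[0]
    edges = np.concatenate(
        (np.full((n, 1), -1, dtype=np.int64), floors, np.full((n, 1), L - 1)),
        axis=1,
    )
    P = np.concatenate(([0.0], hist._cum_p))
    M = np.concatenate(([0.0], hist._cum_jp))
    lo, hi = edges[:, :-1] + 1, edges[:, 1:] + 1
    w = P[hi] - P[lo]
    m = M[hi] - M[lo]
    # sum m^2/w - mu_T^2 == sum w*(mu - mu_T)^2 when sum w == 1
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(w > 0.0, m * m / np.where(w > 0.0, w, 1.0), 0.0)
    J = terms.sum(axis=1) - hist.mean**2
    J = np.maximum(J, 0.0)
    return J[0] if squeeze else J


def brute_force_thresholds(
    hist: Histogram, k: int, max_combinations: int = 10**6
) -> tuple[ThresholdSet, float]:
    """Exhaustively maximize J over all integer threshold combinations.

    Candidates are the integers ``1..L-1``; ties are broken by the
    lexicographically smallest threshold vector so the result is a
    deterministic oracle for validating the metaheuristics.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    L = hist.n_levels
    n_comb = math.comb(L - 1, k)
    if n_comb > max_combinations:
        raise ValueError("instance too large for oracle")
    best_J = -np.inf
    best_combo: tuple[int, ...] | None = None
    chunk = 200_000
    it = itertools.combinations(range(1, L), k)
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        arr = np.asarray(block, dtype=float)
        J = evaluate_thresholds(hist, arr)
        i = int(np.argmax(J))  # argmax returns the first (lex-smallest) max
        if J[i] > best_J:
            best_J = float(J[i])
            best_combo = block[i]
    assert best_combo is not None
    return ThresholdSet(np.asarray(best_combo, dtype=float), n_levels=L), best_J


def canonical_bins(hist: Histogram, thresholds: ThresholdSet) -> np.ndarray:
    """Map thresholds to the lexicographically smallest equivalent bins.

    The objective is piecewise-constant: sliding a threshold left across
    zero-probability bins leaves every class's pixel membership unchanged.
    Reporting the left edge of each such plateau gives every optimizer and
    the exhaustive oracle a common, deterministic integer representation of
    the partition they found.
    """
    floors = np.clip(thresholds.floors, 1, hist.n_levels - 1)
    P = hist._cum_p
    out = np.searchsorted(P, P[floors], side="left")
    return np.maximum(out, 1).astype(np.int64)
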