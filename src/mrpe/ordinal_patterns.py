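"""Ordinal (Bandt–Pompe) patterns and their plain and weighted distributions.

A window of ``m`` values taken with delay ``tau`` from a series is mapped to
the permutation of its positions sorted by ascending value — its ordinal
pattern, or "π-type".  Ties are broken by ascending position (a stable sort),
the standard Bandt–Pompe convention.  Counting patterns over all windows gives
a probability distribution over (at most) the ``m!`` permutations; weighting
each window by its population variance instead of counting it once gives the
weighted distribution, which lets amplitude structure contribute alongside
pure order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import (
    DegenerateSeriesError,
    InvalidInputError,
    LengthError,
    ParameterError,
    SeriesLengthWarning,
)

__all__ = [
    "OrdinalPattern",
    "EmbeddingWindow",
    "PatternDistribution",
    "pattern_of",
    "enumerate_windows",
    "pattern_distribution",
    "weighted_pattern_distribution",
    "pattern_index",
    "pattern_from_index",
]


@dataclass(frozen=True, order=True)
class OrdinalPattern:
    """A π-type: positions of the window sorted by ascending value, 1-based.

    ``order[k]`` is the (1-based) position inside the window of the (k+1)-th
    smallest value.  Two windows related by any strictly increasing
    transformation map to the same pattern.
    """

    order: tuple[int, ...]

    def __post_init__(self) -> None:
        m = len(self.order)
        if m < 2:
            raise ParameterError(f"pattern length must be >= 2, got {m}")
        if sorted(self.order) != list(range(1, m + 1)):
            raise InvalidInputError(
                f"order {self.order} is not a permutation of 1..{m}"
            )

    @property
    def m(self) -> int:
        return len(self.order)

    def rank_vector(self) -> tuple[int, ...]:
        """Inverse-permutation view: ``rank_vector()[i]`` is the 1-based rank
        of the window's i-th value.  Some libraries encode patterns this way;
        the conversion is provided to avoid silent convention mismatch."""
        ranks = [0] * self.m
        for rank, pos in enumerate(self.order, start=1):
            ranks[pos - 1] = rank
        return tuple(ranks)


@dataclass(frozen=True)
class EmbeddingWindow:
    """One delay-embedded window (x_j, x_{j+τ}, ..., x_{j+(m−1)τ}).

    ``start`` is 1-based, mirroring the index convention of the defining
    formulas.  ``weight`` is the population variance (divide-by-m) of the
    window values; it is zero iff all values are equal.
    """

    start: int
    values: tuple[float, ...]
    mean: float
    weight: float

    def pattern(self) -> OrdinalPattern:
        return pattern_of(self.values)


@dataclass(frozen=True)
class PatternDistribution:
    """Probability mass over observed ordinal patterns for fixed (m, τ).

    Unobserved patterns are absent (implicitly zero).  ``kind`` is "plain"
    (relative frequencies) or "weighted" (variance-weighted frequencies).
    Insertion order of ``probs`` is ascending lexicographic pattern index, so
    iteration (and hence any floating-point reduction over it) is
    deterministic.
    """

    m: int
    tau: int
    kind: str
    probs: dict[OrdinalPattern, float] = field(compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("plain", "weighted"):
            raise ParameterError(f"kind must be 'plain' or 'weighted', got {self.kind!r}")
        total = math.fsum(self.probs.values())
        if abs(total - 1.0) > 1e-12:
            raise InvalidInputError(f"probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.probs.values()):
            raise InvalidInputError("negative probability")
        if len(self.probs) > math.factorial(self.m):
            raise InvalidInputError("more patterns than m! permutations")

    def probabilities(self) -> np.ndarray:
        """Observed probabilities in ascending pattern-index order."""
        return np.fromiter(self.probs.values(), dtype=float, count=len(self.probs))

    def __iter__(self) -> Iterator[OrdinalPattern]:
        return iter(self.probs)


def pattern_of(window_values: Sequence[float]) -> OrdinalPattern:
    """Ordinal pattern of a window: positions sorted by ascending value.

    Ties are broken by ascending position (stable sort), so e.g. a constant
    window maps to the identity permutation.
    """
    values = np.asarray(window_values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ParameterError(f"window must hold m >= 2 values, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("window contains non-finite values")
    order = np.argsort(values, kind="stable") + 1
    return OrdinalPattern(tuple(int(r) for r in order))


def _check_embedding(T: int, m: int, tau: int) -> int:
    """Validate (m, tau) against series length; return the window count."""
    if m < 2:
        raise ParameterError(f"embedding dimension m must be >= 2, got {m}")
    if tau < 1:
        raise ParameterError(f"delay tau must be >= 1, got {tau}")
    n = T - (m - 1) * tau
    if n < 1:
        raise LengthError(
            f"series of length {T} is too short for m={m}, tau={tau}; "
            f"need T >= {(m - 1) * tau + 1}",
            required=(m - 1) * tau + 1,
            actual=T,
        )
    return n


def _series_values(series) -> np.ndarray:
    # Accept RRSeries (duck-typed via .values) or any 1-D sequence.
    values = getattr(series, "values", series)
    return np.asarray(values, dtype=float)


def _window_matrix(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = x.size - (m - 1) * tau
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _codes_and_weights(x: np.ndarray, m: int, tau: int) -> tuple[np.ndarray, np.ndarray]:
    """Lexicographic pattern code and variance weight of every window.

    Codes are Lehmer ranks of the position-permutation, consistent with
    :func:`pattern_index`.  This is the vectorised core shared by the plain
    and weighted distribution builders.
    """
    W = _window_matrix(x, m, tau)
    order = np.argsort(W, axis=1, kind="stable")  # 0-based positions by value
    codes = np.zeros(W.shape[0], dtype=np.int64)
    for i in range(m - 1):
        smaller_later = (order[:, i + 1 :] < order[:, i : i + 1]).sum(axis=1)
        codes = codes * (m - i) + smaller_later
    means = W.mean(axis=1)
    weights = _window_weights(W, means)
    return codes, weights


def _window_weights(W: np.ndarray, means: np.ndarray) -> np.ndarray:
    weights = ((W - means[:, None]) ** 2).mean(axis=1)
    # Exactly zero for constant windows (the mean round-off otherwise leaves
    # a ~1e-32 residue), honouring "weight = 0 iff all values are equal".
    weights[np.ptp(W, axis=1) == 0] = 0.0
    return weights


def enumerate_windows(series, m: int, tau: int) -> list[EmbeddingWindow]:
    """All T − (m−1)τ delay-embedded windows, with mean and variance weight."""
    x = _series_values(series)
    _check_embedding(x.size, m, tau)
    W = _window_matrix(x, m, tau)
    means = W.mean(axis=1)
    weights = _window_weights(W, means)
    return [
        EmbeddingWindow(
            start=j + 1,
            values=tuple(float(v) for v in W[j]),
            mean=float(means[j]),
            weight=float(weights[j]),
        )
        for j in range(W.shape[0])
    ]


def _distribution_arrays(
    x: np.ndarray, m: int, tau: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """(plain counts, summed weights, window count) indexed by pattern code."""
    n = _check_embedding(x.size, m, tau)
    codes, weights = _codes_and_weights(x, m, tau)
    n_patterns = math.factorial(m)
    counts = np.bincount(codes, minlength=n_patterns)
    weight_sums = np.bincount(codes, weights=weights, minlength=n_patterns)
    return counts, weight_sums, n


def _warn_if_short(T: int, m: int) -> None:
    threshold = 5 * math.factorial(m)
    if T <= threshold:
        warnings.warn(
            f"series length T={T} does not satisfy T > 5*m! = {threshold} for "
            f"m={m}; the pattern distribution may be unreliable",
            SeriesLengthWarning,
            stacklevel=3,
        )


def _probs_to_distribution(
    probs: np.ndarray, m: int, tau: int, kind: str
) -> PatternDistribution:
    mapping = {
        pattern_from_index(int(code), m): float(p)
        for code, p in enumerate(probs)
        if p > 0
    }
    return PatternDistribution(m=m, tau=tau, kind=kind, probs=mapping)


def pattern_distribution(series, m: int, tau: int) -> PatternDistribution:
    """Relative frequency p_τ(π) of each observed pattern."""
    x = _series_values(series)
    counts, _, n = _distribution_arrays(x, m, tau)
    _warn_if_short(x.size, m)
    return _probs_to_distribution(counts / n, m, tau, "plain")


def weighted_pattern_distribution(series, m: int, tau: int) -> PatternDistribution:
    """Variance-weighted relative frequency p_ωτ(π) of each observed pattern.

    Raises :class:`DegenerateSeriesError` when every window has zero variance
    (e.g. a constant series), since the weighted frequencies are then 0/0.
    """
    x = _series_values(series)
    _, weight_sums, _ = _distribution_arrays(x, m, tau)
    _warn_if_short(x.size, m)
    total = weight_sums.sum()
    if total <= 0.0:
        raise DegenerateSeriesError(
            "total window weight is zero (constant series?); "
            "weighted frequencies are undefined"
        )
    return _probs_to_distribution(weight_sums / total, m, tau, "weighted")


def pattern_index(pattern: OrdinalPattern) -> int:
    """Lexicographic rank of the pattern's permutation, in 0..m!−1."""
    order = [r - 1 for r in pattern.order]
    m = len(order)
    rank = 0
    for i in range(m - 1):
        smaller_later = sum(1 for j in range(i + 1, m) if order[j] < order[i])
        rank = rank * (m - i) + smaller_later
    return rank


def pattern_from_index(index: int, m: int) -> OrdinalPattern:
    """Inverse of :func:`pattern_index`."""
    if not 0 <= index < math.factorial(m):
        raise ParameterError(f"index {index} out of range for m={m}")
    # Decode Lehmer digits, then pick remaining symbols.
    digits = []
    rem = index
    for i in range(m - 1, 0, -1):
        digits.append(rem // math.factorial(i))
        rem %= math.factorial(i)
    digits.append(0)
    symbols = list(range(1, m + 1))
    order = [symbols.pop(d) for d in digits]
    return OrdinalPattern(tuple(order))
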