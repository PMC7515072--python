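"""Normalized permutation, Rényi, and weighted Rényi permutation entropy.

All values are normalized by log(m!) — the maximum attainable over m!
patterns — so they live in [0, 1] and are independent of the logarithm base.
The Rényi order α interpolates: α < 1 emphasises rare patterns, α > 1
frequent ones; α → 1 recovers Shannon permutation entropy and α → ∞ the
permutation min-entropy −log(max p)/log(m!).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import ParameterError
from .ordinal_patterns import PatternDistribution

__all__ = [
    "EntropyValue",
    "ALPHA_SHANNON_TOL",
    "permutation_entropy",
    "renyi_entropy",
    "weighted_renyi_entropy",
    "entropy_from_probabilities",
]

logger = logging.getLogger(__name__)

# |alpha - 1| below this dispatches to the Shannon limit to avoid the
# catastrophic cancellation in log(sum p^alpha)/(1 - alpha).
ALPHA_SHANNON_TOL = 1e-6


@dataclass(frozen=True)
class EntropyValue:
    """A normalized entropy together with the parameters that produced it.

    ``alpha`` = 1.0 marks the Shannon (permutation-entropy) limit.  ``scale``
    is the coarse-graining factor of the series the distribution came from
    (1 for a raw series).
    """

    value: float
    alpha: float
    m: int
    tau: int
    scale: int = 1
    weighted: bool = False

    def __post_init__(self) -> None:
        if not -1e-12 <= self.value <= 1.0 + 1e-12:
            raise ParameterError(f"normalized entropy {self.value} outside [0, 1]")

    def parameters(self) -> tuple:
        return (self.alpha, self.m, self.tau, self.scale, self.weighted)


def _normalized_shannon(probs: np.ndarray, m: int) -> float:
    p = probs[probs > 0]
    return float(-(p * np.log(p)).sum() / math.log(math.factorial(m)))


def _normalized_renyi(probs: np.ndarray, m: int, alpha: float) -> float:
    p = probs[probs > 0]  # 0^alpha = 0 for all alpha > 0
    # log-domain sum keeps large alpha (min-entropy regime) from underflowing
    h = logsumexp(alpha * np.log(p)) / (1.0 - alpha)
    return float(h) / math.log(math.factorial(m))


def entropy_from_probabilities(probs: np.ndarray, m: int, alpha: float) -> float:
    """Normalized order-α entropy of a probability vector (zeros allowed).

    Shared by the distribution-based API and the vectorised grid evaluator so
    both produce bit-identical values.
    """
    if alpha <= 0:
        raise ParameterError(f"Rényi order alpha must be > 0, got {alpha}")
    if abs(alpha - 1.0) < ALPHA_SHANNON_TOL:
        return _normalized_shannon(probs, m)
    # Guard tiny negative round-off for near-degenerate distributions.
    return min(max(_normalized_renyi(probs, m, alpha), 0.0), 1.0)


def permutation_entropy(dist: PatternDistribution) -> EntropyValue:
    """Shannon entropy of the pattern distribution, normalized by log(m!)."""
    value = _normalized_shannon(dist.probabilities(), dist.m)
    return EntropyValue(
        value=value, alpha=1.0, m=dist.m, tau=dist.tau,
        weighted=(dist.kind == "weighted"),
    )


def renyi_entropy(dist: PatternDistribution, alpha: float) -> EntropyValue:
    """Order-α Rényi entropy of the pattern distribution, normalized.

    H_α = log(Σ_π p(π)^α) / (1 − α), divided by log(m!).  The sum runs over
    observed patterns only.  α within ``ALPHA_SHANNON_TOL`` of 1 dispatches
    to :func:`permutation_entropy`.
    """
    if alpha <= 0:
        raise ParameterError(f"Rényi order alpha must be > 0, got {alpha}")
    if abs(alpha - 1.0) < ALPHA_SHANNON_TOL:
        logger.debug("alpha=%s within tolerance of 1; using Shannon limit", alpha)
        return permutation_entropy(dist)
    value = entropy_from_probabilities(dist.probabilities(), dist.m, alpha)
    return EntropyValue(
        value=value, alpha=alpha, m=dist.m, tau=dist.tau,
        weighted=(dist.kind == "weighted"),
    )


def weighted_renyi_entropy(dist: PatternDistribution, alpha: float) -> EntropyValue:
    """Rényi entropy of a *weighted* pattern distribution (same formula)."""
    if dist.kind != "weighted":
        raise ParameterError("weighted_renyi_entropy requires a weighted distribution")
    return renyi_entropy(dist, alpha)
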