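"""Coarse-graining and multiscale (weighted) Rényi permutation entropy.

The coarse-grained series at scale ``s`` replaces the series by its
non-overlapping block means of length ``s`` (trailing remainder dropped);
MRPE/WMRPE is then simply RPE/WRPE of that series, giving a four-parameter
family indexed by (s, τ, m, α).  ``entropy_grid`` sweeps (s, τ) with the
coarse series computed once per scale, the dominant cost being one stable
argsort of all windows per cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import RRSeries
from .entropy_measures import EntropyValue, entropy_from_probabilities, renyi_entropy
from .errors import LengthError, ParameterError
from .ordinal_patterns import (
    _distribution_arrays,
    pattern_distribution,
    weighted_pattern_distribution,
)

__all__ = [
    "EntropyGrid",
    "coarse_grain",
    "mrpe",
    "wmrpe",
    "entropy_grid",
    "entropy_surfaces",
    "group_mean_grid",
    "grid_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_S = tuple(range(1, 21))
DEFAULT_TAU = tuple(range(1, 101))


@dataclass(frozen=True)
class EntropyGrid:
    """Normalized entropies on an (s, τ) lattice for fixed (m, α, weighted).

    ``values[i, j]`` is the entropy at ``s_values[i]``, ``tau_values[j]``;
    NaN marks a cell whose length precondition failed.  ``subject`` and
    ``group`` label the source series; ``is_mean`` flags group averages.
    """

    m: int
    alpha: float
    weighted: bool
    s_values: tuple[int, ...]
    tau_values: tuple[int, ...]
    values: np.ndarray = field(compare=False)
    subject: str = ""
    group: str = ""
    is_mean: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.s_values), len(self.tau_values)):
            raise ParameterError(
                f"grid shape {values.shape} does not match "
                f"({len(self.s_values)}, {len(self.tau_values)})"
            )
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ParameterError("grid holds entropies outside [0, 1]")

    def parameters(self) -> tuple:
        return (self.m, self.alpha, self.weighted, self.s_values, self.tau_values)

    def at(self, s: int, tau: int) -> float:
        return float(self.values[self.s_values.index(s), self.tau_values.index(tau)])


def coarse_grain(series: RRSeries, s: int) -> RRSeries:
    """Non-overlapping block means of length ``s``; length becomes ⌊T/s⌋."""
    if s < 1:
        raise ParameterError(f"scale s must be >= 1, got {s}")
    T = len(series)
    if T < s:
        raise ParameterError(f"series of length {T} is shorter than scale s={s}")
    if s == 1:
        return series
    n_blocks = T // s
    coarse = series.values[: n_blocks * s].reshape(n_blocks, s).mean(axis=1)
    return RRSeries(coarse, subject=series.subject, group=series.group)


def _check_grain_length(series: RRSeries, s: int, m: int, tau: int) -> None:
    needed = (m - 1) * tau + 1
    available = len(series) // s
    if available < needed:
        raise LengthError(
            f"coarse-grained length floor({len(series)}/{s}) = {available} is "
            f"below the (m-1)*tau + 1 = {needed} required for s={s}, m={m}, "
            f"tau={tau}",
            required=needed,
            actual=available,
        )


def mrpe(series: RRSeries, s: int, alpha: float, m: int, tau: int) -> EntropyValue:
    """Multiscale RPE: the Rényi permutation entropy of the scale-``s`` series."""
    _check_grain_length(series, s, m, tau)
    value = renyi_entropy(pattern_distribution(coarse_grain(series, s), m, tau), alpha)
    return replace(value, scale=s)


def wmrpe(series: RRSeries, s: int, alpha: float, m: int, tau: int) -> EntropyValue:
    """Weighted multiscale RPE (variance-weighted pattern frequencies)."""
    _check_grain_length(series, s, m, tau)
    dist = weighted_pattern_distribution(coarse_grain(series, s), m, tau)
    return replace(renyi_entropy(dist, alpha), scale=s)


def entropy_surfaces(
    series: RRSeries,
    m: int,
    alphas: tuple[float, ...],
    s_values: tuple[int, ...] = DEFAULT_S,
    tau_values: tuple[int, ...] = DEFAULT_TAU,
    weighted_flags: tuple[bool, ...] = (False, True),
) -> dict[tuple[float, bool], EntropyGrid]:
    """Evaluate every (α, weighted) surface in one sweep of the (s, τ) grid.

    The expensive work — coarse-graining, window sorting, pattern counting —
    depends only on (s, τ, m) and is shared across all requested entropies,
    so scanning several α values costs little more than one.  Cells whose
    length precondition fails (or whose total weight is zero for a weighted
    surface) become NaN; their count is logged.
    """
    s_values = tuple(int(s) for s in s_values)
    tau_values = tuple(int(t) for t in tau_values)
    if not s_values or not tau_values or not alphas:
        raise ParameterError("s_values, tau_values and alphas must be non-empty")
    if any(s < 1 for s in s_values) or any(t < 1 for t in tau_values):
        raise ParameterError("s and tau values must be >= 1")
    shape = (len(s_values), len(tau_values))
    surfaces = {
        (float(a), w): np.full(shape, np.nan)
        for a in alphas
        for w in weighted_flags
    }
    missing = 0
    n_patterns = math.factorial(m)
    for i, s in enumerate(s_values):  # coarse series computed once per s
        if len(series) < s:
            missing += len(tau_values) * len(surfaces)
            continue
        coarse = coarse_grain(series, s).values
        for j, tau in enumerate(tau_values):
            if coarse.size < (m - 1) * tau + 1:
                missing += len(surfaces)
                continue
            counts, weight_sums, n = _distribution_arrays(coarse, m, tau)
            probs = {False: counts / n}
            total_w = weight_sums.sum()
            if total_w > 0:
                probs[True] = weight_sums / total_w
            for (a, w), grid in surfaces.items():
                if w and total_w <= 0:
                    missing += 1
                    continue
                grid[i, j] = entropy_from_probabilities(probs[w], m, a)
    if missing:
        logger.info(
            "%s: %d grid cells missing (length/weight preconditions)",
            series.subject or "series", missing,
        )
    return {
        (a, w): EntropyGrid(
            m=m, alpha=a, weighted=w, s_values=s_values, tau_values=tau_values,
            values=grid, subject=series.subject, group=series.group,
        )
        for (a, w), grid in surfaces.items()
    }


def entropy_grid(
    series: RRSeries,
    m: int,
    alpha: float,
    weighted: bool = False,
    s_values: tuple[int, ...] = DEFAULT_S,
    tau_values: tuple[int, ...] = DEFAULT_TAU,
) -> EntropyGrid:
    """MRPE (or WMRPE) of one series over the (s, τ) lattice."""
    surfaces = entropy_surfaces(
        series, m, (alpha,), s_values, tau_values, (weighted,)
    )
    return surfaces[(float(alpha), weighted)]


def group_mean_grid(grids: list[EntropyGrid]) -> EntropyGrid:
    """Cell-wise arithmetic mean over subjects sharing grid parameters.

    A cell is missing in the mean if it is missing for any subject.  This is
    the average-surface view of a group, not the entropy of pooled series.
    """
    if not grids:
        raise ParameterError("need at least one grid")
    params = grids[0].parameters()
    if any(g.parameters() != params for g in grids[1:]):
        raise ParameterError("grids do not share (m, alpha, weighted, s, tau)")
    stacked = np.stack([g.values for g in grids])
    mean = stacked.mean(axis=0)  # NaN propagates: missing-if-any-missing
    groups = {g.group for g in grids}
    return EntropyGrid(
        m=grids[0].m, alpha=grids[0].alpha, weighted=grids[0].weighted,
        s_values=grids[0].s_values, tau_values=grids[0].tau_values,
        values=mean,
        subject="mean", group=groups.pop() if len(groups) == 1 else "mixed",
        is_mean=True,
    )


def grid_frame(grid: EntropyGrid) -> pd.DataFrame:
    """Long-format export: subject, group, m, alpha, weighted, s, tau, entropy.

    Missing cells become empty fields when written as CSV (NaN in the frame).
    Rows are in ascending (s, τ) order.
    """
    s_idx, tau_idx = np.meshgrid(
        np.arange(len(grid.s_values)), np.arange(len(grid.tau_values)), indexing="ij"
    )
    return pd.DataFrame(
        {
            "subject": grid.subject,
            "group": grid.group,
            "m": grid.m,
            "alpha": grid.alpha,
            "weighted": grid.weighted,
            "s": np.asarray(grid.s_values)[s_idx.ravel()],
            "tau": np.asarray(grid.tau_values)[tau_idx.ravel()],
            "entropy": grid.values.ravel(),
        }
    )
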