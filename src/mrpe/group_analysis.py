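"""Three-group differentiation by entropy-interval disjointness.

For each group G and fixed parameters (s, α, m, τ), the per-subject
entropies span a closed interval [m_G, M_G] between the minimum and maximum
subject value.  Two groups are differentiated when their intervals are
disjoint; three groups are differentiated simultaneously when the intervals
are pairwise disjoint, which forces a total order G1 > G2 > G3.  The
"difference" at such a point is the smaller of the two adjacent gaps —
the minimum distance between any two values from different groups.  The
scan evaluates this verdict at every (s, τ) grid cell.  This is a
descriptive criterion; no statistical inference is attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy_measures import EntropyValue
from .errors import ParameterError
from .multiscale import EntropyGrid

__all__ = [
    "GroupInterval",
    "DifferentiationResult",
    "ScanSummary",
    "group_interval",
    "differentiate_three",
    "scan_differentiation",
    "scan_frame",
]


@dataclass(frozen=True)
class GroupInterval:
    """[min, max] of per-subject entropies in one group at fixed parameters."""

    group: str
    lo: float
    hi: float
    n_subjects: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ParameterError(f"interval lo={self.lo} > hi={self.hi}")
        if not (0 - 1e-12 <= self.lo and self.hi <= 1 + 1e-12):
            raise ParameterError("interval endpoints outside [0, 1]")


@dataclass(frozen=True)
class DifferentiationResult:
    """Verdict at one (s, τ) point: disjointness, ordering, minimum gap."""

    s: int
    tau: int
    m: int
    alpha: float
    weighted: bool
    differentiated: bool
    ordering: tuple[str, ...]  # groups by descending interval; () if not
    difference: float  # min adjacent gap; 0 if not differentiated

    def __post_init__(self) -> None:
        if self.differentiated != (self.difference > 0):
            raise ParameterError("difference must be > 0 iff differentiated")


@dataclass(frozen=True)
class ScanSummary:
    """Aggregate of a full (s, τ) differentiation scan."""

    n_differentiated: int
    n_evaluated: int
    n_skipped: int  # cells with any missing subject value
    max_difference: float
    argmax: tuple[int, int] | None  # first maximiser in ascending (s, tau)
    all_argmax: tuple[tuple[int, int], ...]
    ordering_at_max: tuple[str, ...]


def group_interval(entropies: list[EntropyValue], group: str = "") -> GroupInterval:
    """Min/max envelope of one group's per-subject entropies."""
    if not entropies:
        raise ParameterError("group has no subjects")
    params = entropies[0].parameters()
    if any(e.parameters() != params for e in entropies[1:]):
        raise ParameterError("entropies do not share (alpha, m, tau, s, weighted)")
    values = [e.value for e in entropies]
    return GroupInterval(
        group=group, lo=min(values), hi=max(values), n_subjects=len(values)
    )


def _differentiate(
    intervals: list[GroupInterval],
    s: int = 0,
    tau: int = 0,
    m: int = 0,
    alpha: float = 0.0,
    weighted: bool = False,
) -> DifferentiationResult:
    if len(intervals) != 3:
        raise ParameterError(f"exactly three groups required, got {len(intervals)}")
    # Descending by interval; closed intervals touching at an endpoint are
    # NOT disjoint, so a gap must be strictly positive.
    ordered = sorted(intervals, key=lambda iv: (iv.lo, iv.hi), reverse=True)
    gaps = [
        ordered[k].lo - ordered[k + 1].hi  # lo of upper minus hi of lower
        for k in range(2)
    ]
    if min(gaps) > 0:
        return DifferentiationResult(
            s=s, tau=tau, m=m, alpha=alpha, weighted=weighted,
            differentiated=True,
            ordering=tuple(iv.group for iv in ordered),
            difference=min(gaps),
        )
    return DifferentiationResult(
        s=s, tau=tau, m=m, alpha=alpha, weighted=weighted,
        differentiated=False, ordering=(), difference=0.0,
    )


def differentiate_three(intervals: list[GroupInterval]) -> DifferentiationResult:
    """Pairwise-disjointness verdict for exactly three group intervals."""
    return _differentiate(list(intervals))


def scan_differentiation(
    group_grids: dict[str, list[EntropyGrid]],
) -> tuple[list[DifferentiationResult], ScanSummary]:
    """Differentiation verdict at every (s, τ) cell of three subject cohorts.

    ``group_grids`` maps each of exactly three group names to that group's
    per-subject grids; all grids must share (m, α, weighted, s, τ).  Cells
    where any subject is missing are skipped (counted in the summary).
    Results come back in ascending (s, τ) order.
    """
    if len(group_grids) != 3:
        raise ParameterError(f"exactly three groups required, got {len(group_grids)}")
    all_grids = [g for grids in group_grids.values() for g in grids]
    if not all_grids:
        raise ParameterError("no grids supplied")
    params = all_grids[0].parameters()
    if any(g.parameters() != params for g in all_grids[1:]):
        raise ParameterError("grids do not share (m, alpha, weighted, s, tau)")
    m, alpha, weighted, s_values, tau_values = params

    stacks = {
        name: np.stack([g.values for g in grids])
        for name, grids in group_grids.items()
    }
    results: list[DifferentiationResult] = []
    skipped = 0
    for i, s in enumerate(s_values):
        for j, tau in enumerate(tau_values):
            cell = {name: stack[:, i, j] for name, stack in stacks.items()}
            if any(np.isnan(v).any() for v in cell.values()):
                skipped += 1
                continue
            intervals = [
                GroupInterval(
                    group=name,
                    lo=float(v.min()),
                    hi=float(v.max()),
                    n_subjects=v.size,
                )
                for name, v in cell.items()
            ]
            results.append(
                _differentiate(intervals, s=s, tau=tau, m=m, alpha=alpha,
                               weighted=weighted)
            )

    hits = [r for r in results if r.differentiated]
    if hits:
        max_diff = max(r.difference for r in hits)
        maximisers = tuple(
            (r.s, r.tau) for r in hits if r.difference == max_diff
        )
        first = [r for r in hits if (r.s, r.tau) == maximisers[0]][0]
        summary = ScanSummary(
            n_differentiated=len(hits),
            n_evaluated=len(results),
            n_skipped=skipped,
            max_difference=max_diff,
            argmax=maximisers[0],
            all_argmax=maximisers,
            ordering_at_max=first.ordering,
        )
    else:
        summary = ScanSummary(
            n_differentiated=0, n_evaluated=len(results), n_skipped=skipped,
            max_difference=0.0, argmax=None, all_argmax=(), ordering_at_max=(),
        )
    return results, summary


def scan_frame(results: list[DifferentiationResult]) -> pd.DataFrame:
    """Tabular export: m, alpha, weighted, s, tau, differentiated, ordering,
    difference — one row per evaluated grid point."""
    return pd.DataFrame(
        {
            "m": [r.m for r in results],
            "alpha": [r.alpha for r in results],
            "weighted": [r.weighted for r in results],
            "s": [r.s for r in results],
            "tau": [r.tau for r in results],
            "differentiated": [r.differentiated for r in results],
            "ordering": [">".join(r.ordering) for r in results],
            "difference": [r.difference for r in results],
        }
    )
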