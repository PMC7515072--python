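"""Interval construction, three-group disjointness, and the (s, tau) scan."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mrpe
from mrpe.errors import ParameterError


def ev(value, **kwargs):
    params = dict(alpha=2.0, m=3, tau=1, scale=1, weighted=False)
    params.update(kwargs)
    return mrpe.EntropyValue(value=value, **params)


def iv(group, lo, hi, n=5):
    return mrpe.GroupInterval(group=group, lo=lo, hi=hi, n_subjects=n)


class TestGroupInterval:
    def test_min_max(self):
        interval = mrpe.group_interval([ev(0.62), ev(0.71), ev(0.68)], group="H")
        assert (interval.lo, interval.hi) == (0.62, 0.71)
        assert interval.n_subjects == 3

    def test_single_subject(self):
        interval = mrpe.group_interval([ev(0.5)])
        assert interval.lo == interval.hi == 0.5

    def test_mixed_parameters_rejected(self):
        with pytest.raises(ParameterError):
            mrpe.group_interval([ev(0.5), ev(0.6, tau=2)])
        with pytest.raises(ParameterError):
            mrpe.group_interval([])


class TestDifferentiateThree:
    def test_separated_intervals(self):
        result = mrpe.differentiate_three(
            [iv("A", 0.9, 0.95), iv("B", 0.7, 0.8), iv("C", 0.5, 0.6)]
        )
        assert result.differentiated
        assert result.ordering == ("A", "B", "C")
        # min(0.9 - 0.8, 0.7 - 0.6)
        assert result.difference == pytest.approx(0.1)

    def test_overlap_not_differentiated(self):
        result = mrpe.differentiate_three(
            [iv("A", 0.5, 0.7), iv("B", 0.6, 0.8), iv("C", 0.9, 0.95)]
        )
        assert not result.differentiated
        assert result.difference == 0.0 and result.ordering == ()

    def test_touching_closed_intervals_fail(self):
        result = mrpe.differentiate_three(
            [iv("A", 0.5, 0.6), iv("B", 0.6, 0.7), iv("C", 0.8, 0.9)]
        )
        assert not result.differentiated

    def test_wrong_group_count(self):
        with pytest.raises(ParameterError):
            mrpe.differentiate_three([iv("A", 0.1, 0.2), iv("B", 0.3, 0.4)])

    def test_order_invariance(self):
        intervals = [iv("A", 0.9, 0.95), iv("B", 0.7, 0.8), iv("C", 0.5, 0.6)]
        base = mrpe.differentiate_three(intervals)
        for perm in itertools.permutations(intervals):
            result = mrpe.differentiate_three(list(perm))
            assert result.ordering == base.ordering
            assert result.difference == base.difference

    @settings(derandomize=True, max_examples=200)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_disjointness_oracle(self, seed):
        """Verdict matches a brute-force check over all cross-group value
        pairs: two groups are disjoint iff every value of one strictly
        exceeds every value of the other."""
        rng = np.random.default_rng(seed)
        groups = {
            name: rng.uniform(0, 1, size=rng.integers(1, 6))
            for name in ("A", "B", "C")
        }
        intervals = [
            iv(name, values.min(), values.max(), n=values.size)
            for name, values in groups.items()
        ]
        result = mrpe.differentiate_three(intervals)

        def disjoint(u, v):
            return all(a < b for a in u for b in v) or all(
                b < a for a in u for b in v
            )

        expected = all(
            disjoint(groups[p], groups[q])
            for p, q in itertools.combinations(groups, 2)
        )
        assert result.differentiated == expected
        if expected:
            cross_gaps = [
                min(abs(a - b) for a in groups[p] for b in groups[q])
                for p, q in itertools.combinations(groups, 2)
            ]
            # the minimum cross-group distance over the two adjacent pairs
            assert result.difference == pytest.approx(sorted(cross_gaps)[0])

    @settings(derandomize=True, max_examples=100)
    @given(
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        shift=st.floats(min_value=-0.3, max_value=0.3),
    )
    def test_difference_translation_invariant(self, seed, shift):
        rng = np.random.default_rng(seed)
        lows = np.sort(rng.uniform(0.35, 0.65, size=3))[::-1]
        intervals = [
            iv(name, lo, lo + 0.02) for name, lo in zip("ABC", lows)
        ]
        shifted = [
            iv(interval.group, interval.lo + shift, interval.hi + shift)
            for interval in intervals
        ]
        a = mrpe.differentiate_three(intervals)
        b = mrpe.differentiate_three(shifted)
        assert a.difference == pytest.approx(b.difference, abs=1e-12)

    def test_monotone_degradation(self):
        """Enlarging any interval never increases the difference."""
        base = [iv("A", 0.9, 0.95), iv("B", 0.7, 0.8), iv("C", 0.5, 0.6)]
        d0 = mrpe.differentiate_three(base).difference
        for k, (dlo, dhi) in itertools.product(range(3), [(-0.05, 0), (0, 0.05)]):
            grown = list(base)
            grown[k] = iv(base[k].group, base[k].lo + dlo, base[k].hi + dhi)
            assert mrpe.differentiate_three(grown).difference <= d0 + 1e-12


def constant_grid(fill, group, subject="s"):
    return mrpe.EntropyGrid(
        m=3, alpha=2.0, weighted=False, s_values=(1, 2), tau_values=(1, 2, 3),
        values=np.full((2, 3), fill), subject=subject, group=group,
    )


class TestScan:
    def test_constant_grids_all_differentiated(self):
        groups = {
            "lo": [constant_grid(0.2, "lo")],
            "mid": [constant_grid(0.5, "mid")],
            "hi": [constant_grid(0.8, "hi")],
        }
        results, summary = mrpe.scan_differentiation(groups)
        assert summary.n_differentiated == 6  # |s| * |tau|
        assert summary.max_difference == pytest.approx(0.3)
        assert summary.ordering_at_max == ("hi", "mid", "lo")
        assert [(r.s, r.tau) for r in results] == [
            (1, 1), (1, 2), (1, 3), (2, 1), (2, 2), (2, 3),
        ]

    def test_identical_grids_zero_points(self):
        groups = {n: [constant_grid(0.5, n)] for n in ("a", "b", "c")}
        _, summary = mrpe.scan_differentiation(groups)
        assert summary.n_differentiated == 0
        assert summary.argmax is None

    def test_missing_cells_skipped(self):
        values = np.full((2, 3), 0.8)
        values[1, 2] = np.nan
        holed = mrpe.EntropyGrid(
            m=3, alpha=2.0, weighted=False, s_values=(1, 2),
            tau_values=(1, 2, 3), values=values, group="hi",
        )
        groups = {
            "lo": [constant_grid(0.2, "lo")],
            "mid": [constant_grid(0.5, "mid")],
            "hi": [holed],
        }
        _, summary = mrpe.scan_differentiation(groups)
        assert summary.n_skipped == 1
        assert summary.n_evaluated == 5

    def test_group_count_enforced(self):
        with pytest.raises(ParameterError):
            mrpe.scan_differentiation({"a": [constant_grid(0.1, "a")]})

    def test_synthetic_three_regimes_scan(self, synthetic_cohorts):
        """The pinned-seed surrogate cohorts separate at many grid points,
        with the iid-like (AF-like) group on top, and the scan is
        reproducible run-to-run."""
        s_values, tau_values = tuple(range(1, 6)), tuple(range(1, 11))

        def run():
            groups = {
                name: [
                    mrpe.entropy_grid(subj, 3, 2.0, False, s_values, tau_values)
                    for subj in cohort
                ]
                for name, cohort in synthetic_cohorts.items()
            }
            return mrpe.scan_differentiation(groups)

        results1, summary1 = run()
        _, summary2 = run()
        assert summary1.n_differentiated > 0
        assert summary1.max_difference > 0
        assert summary1.ordering_at_max == ("AF", "H", "CHF")
        assert summary1 == summary2


def test_scan_frame_schema():
    groups = {
        "lo": [constant_grid(0.2, "lo")],
        "mid": [constant_grid(0.5, "mid")],
        "hi": [constant_grid(0.8, "hi")],
    }
    results, _ = mrpe.scan_differentiation(groups)
    frame = mrpe.scan_frame(results)
    assert list(frame.columns) == [
        "m", "alpha", "weighted", "s", "tau", "differentiated", "ordering",
        "difference",
    ]
    assert frame["ordering"].iloc[0] == "hi>mid>lo"
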