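import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonalholes.diversity import (
    auto_grid,
    hill_diversity,
    rarefaction_curve,
    rarefied_diversity,
    relative_diversity,
    sample_coverage,
)
from clonalholes.model import UndefinedDiversityError

from .oracles import exact_rarefied_shannon, shannon_hill

small_vectors = st.lists(st.integers(min_value=0, max_value=6), min_size=1,
                         max_size=5).filter(lambda v: 0 < sum(v) <= 12)


class TestHillDiversity:
    @pytest.mark.parametrize(
        "counts, q, expected",
        [
            ([1, 1, 1, 1], 1, 4.0),              # equal abundances: D = S
            ([7], 0, 1.0),
            ([7], 1, 1.0),
            ([7], 2, 1.0),
            ([2, 1, 1], 1, 2 ** 1.5),            # exp(-(.5 ln .5 + 2*.25 ln .25))
            ([2, 1, 1], 2, 1 / 0.375),           # inverse Simpson by hand
            ([5, 3, 2], 0, 3.0),                 # q=0 is richness
        ],
    )
    def test_closed_forms(self, counts, q, expected):
        assert hill_diversity(counts, q) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(small_vectors)
    def test_matches_independent_shannon_formula(self, counts):
        assert hill_diversity(counts, 1) == pytest.approx(
            shannon_hill(counts), rel=1e-12
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(small_vectors, st.floats(0, 5), st.floats(0, 5))
    def test_nonincreasing_in_order_q(self, counts, q1, q2):
        lo, hi = sorted([q1, q2])
        assert hill_diversity(counts, lo) >= hill_diversity(counts, hi) - 1e-9

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(small_vectors, st.integers(2, 50))
    def test_scale_invariance(self, counts, factor):
        scaled = [c * factor for c in counts]
        for q in (0, 1, 2):
            assert hill_diversity(scaled, q) == pytest.approx(
                hill_diversity(counts, q), rel=1e-9
            )

    def test_continuity_at_q_equals_one(self):
        counts = [5, 3, 2, 1]
        d1 = hill_diversity(counts, 1.0)
        assert hill_diversity(counts, 1 + 1e-7) == pytest.approx(d1, rel=1e-5)
        assert hill_diversity(counts, 1 - 1e-7) == pytest.approx(d1, rel=1e-5)

    def test_bounds_between_one_and_richness(self):
        counts = [9, 3, 1, 1]
        for q in (0, 0.5, 1, 2):
            assert 1.0 <= hill_diversity(counts, q) <= 4.0

    def test_empty_vector_is_undefined(self):
        with pytest.raises(UndefinedDiversityError):
            hill_diversity([0, 0], 1)


class TestRarefaction:
    def test_full_depth_subsample_equals_observed(self):
        counts = [5, 3, 2]
        mean, se = rarefied_diversity(counts, m=10, reps=25, seed=0)
        assert mean == pytest.approx(hill_diversity(counts, 1), rel=1e-12)
        assert se == 0.0

    def test_single_molecule_subsample_is_one(self):
        mean, se = rarefied_diversity([1, 1], m=1, reps=50, seed=0)
        assert (mean, se) == (1.0, 0.0)

    def test_converges_to_enumeration_expectation(self):
        # counts (3,1), m=2: compositions (2,0) w.p. 3/6 and (1,1) w.p. 3/6,
        # so E[D] = 0.5*1 + 0.5*2 = 1.5
        assert exact_rarefied_shannon([3, 1], 2) == pytest.approx(1.5)
        mean, se = rarefied_diversity([3, 1], m=2, reps=2000, seed=1)
        assert abs(mean - 1.5) <= 3 * max(se, 1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(small_vectors, st.data())
    def test_monte_carlo_agrees_with_enumeration(self, counts, data):
        n = sum(counts)
        m = data.draw(st.integers(1, n))
        exact = exact_rarefied_shannon(counts, m)
        mean, se = rarefied_diversity(counts, m=m, reps=400, seed=7)
        assert abs(mean - exact) <= 3 * max(se, 1e-9)

    def test_out_of_range_subsample_raises(self):
        with pytest.raises(ValueError):
            rarefied_diversity([2, 1], m=4, reps=10, seed=0)
        with pytest.raises(ValueError):
            rarefied_diversity([2, 1], m=0, reps=10, seed=0)

    def test_curve_final_point_equals_observed(self):
        counts = [5, 3, 2, 1, 1]
        res = rarefaction_curve(counts, [12], reps=10, seed=0)
        assert res.curve[0][1] == pytest.approx(res.d_obs)

    def test_curve_means_nondecreasing_within_monte_carlo_error(self):
        counts = [5, 3, 2, 1, 1]
        res = rarefaction_curve(counts, [2, 4, 8, 12], reps=400, seed=3)
        for (m0, d0, s0), (m1, d1, s1) in zip(res.curve, res.curve[1:]):
            assert d1 >= d0 - 3 * (s0 + s1 + 1e-9)

    def test_curve_rejects_grid_beyond_depth(self):
        with pytest.raises(ValueError):
            rarefaction_curve([2, 1], [2, 5], reps=10, seed=0)

    def test_seeded_determinism_is_bit_identical(self):
        counts = [8, 5, 2, 1]
        a = rarefaction_curve(counts, [4, 8, 16], reps=50, seed=11)
        b = rarefaction_curve(counts, [4, 8, 16], reps=50, seed=11)
        assert a.curve == b.curve

    def test_auto_grid_spans_one_to_n(self):
        grid = auto_grid(1000, k=6)
        assert grid[0] == 1 and grid[-1] == 1000 and grid == sorted(grid)


class TestCoverage:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([2, 2, 2], 1.0),        # no singletons
            ([1, 1, 1, 1], 0.0),     # all singletons, no doubletons
            ([3, 1], 0.75),          # f1=1, f2=0, n=4: 1 - (1/4)*(3/3)
            ([1], 0.0),              # degenerate single singleton
        ],
    )
    def test_known_values(self, counts, expected):
        assert sample_coverage(counts) == pytest.approx(expected)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(small_vectors)
    def test_coverage_in_unit_interval(self, counts):
        assert 0.0 <= sample_coverage(counts) <= 1.0

    def test_empty_sample_raises(self):
        with pytest.raises(UndefinedDiversityError):
            sample_coverage([])


class TestRelativeDiversity:
    def test_reference_normalization(self):
        values = {"a": 4.0, "b": 4.0, "c": 2.0}
        rel = relative_diversity(values, ["a", "b"])
        assert rel == {"a": 1.0, "b": 1.0, "c": 0.5}

    def test_self_reference_is_unity(self):
        assert relative_diversity({"a": 3.7}, ["a"]) == {"a": 1.0}

    def test_two_sample_mutual_reference(self):
        rel = relative_diversity({"a": 3.0, "b": 6.0}, ["a", "b"])
        assert rel["a"] == pytest.approx(2 / 3)
        assert rel["b"] == pytest.approx(4 / 3)

    def test_empty_or_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_diversity({"a": 1.0}, [])
        with pytest.raises(ValueError):
            relative_diversity({"a": 0.0}, ["a"])
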