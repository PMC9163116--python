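"""DTW, epsilon-LCSS and lock-step metrics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tas.similarity import (
    dtw_distance,
    lcss_distance,
    lcss_length,
    lockstep_distance,
    similarity_matrix,
)
from tas.types import SegmentGroup, SegmentId, TrajectoryKind

from _oracles import brute_force_dtw, brute_force_lcss, reference_dtw
from conftest import make_traj

import datetime

short_seq = st.lists(st.integers(-5, 5), min_size=1, max_size=5)
lcss_seq = st.lists(st.integers(-3, 3), min_size=0, max_size=8)


def group_of(trajs, key="g", tau=24.0):
    segs = [
        (SegmentId(datetime.date(2021, 3, 1) + datetime.timedelta(days=i), 0), t)
        for i, t in enumerate(trajs)
    ]
    return SegmentGroup(key=key, resolution_hours=tau, segments=segs)


class TestDTW:
    def test_identity_zero_diagonal_path(self):
        A = make_traj([1.0, 2.0, 5.0, 3.0])
        d, path = dtw_distance(A, A)
        assert d == 0.0
        assert path.pairs == [(i, i) for i in range(1, 5)]

    def test_textbook_example(self):
        d, path = dtw_distance(make_traj([0.0, 1.0, 2.0]), make_traj([0.0, 2.0]))
        assert d == 1.0
        assert path.is_valid(3, 2)

    def test_distance_equals_path_cost(self):
        A, B = make_traj([0.0, 3.0, 1.0, 4.0]), make_traj([1.0, 2.0, 2.0])
        d, path = dtw_distance(A, B)
        cost = sum(abs(A.values[i - 1] - B.values[j - 1]) for i, j in path.pairs)
        assert d == pytest.approx(cost, abs=1e-12)

    @given(short_seq, short_seq)
    @settings(max_examples=250, deadline=None, derandomize=True)
    def test_matches_exhaustive_enumeration(self, a, b):
        A, B = make_traj(a), make_traj(b)
        d, path = dtw_distance(A, B)
        oracle, _, _ = brute_force_dtw(a, b)
        assert d == pytest.approx(oracle, abs=1e-9)
        assert path.is_valid(len(a), len(b))

    @given(short_seq, short_seq)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry(self, a, b):
        dab, _ = dtw_distance(make_traj(a), make_traj(b))
        dba, _ = dtw_distance(make_traj(b), make_traj(a))
        assert dab == pytest.approx(dba, abs=1e-12)

    def test_agrees_with_independent_dp_up_to_length_50(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m, n = rng.integers(1, 51, size=2)
            a, b = rng.normal(size=m), rng.normal(size=n)
            d, _ = dtw_distance(make_traj(a), make_traj(b))
            assert d == pytest.approx(reference_dtw(list(a), list(b)), abs=1e-9)

    def test_2d_gps_pairs(self):
        A = make_traj(np.array([[0.0, 0.0], [1.0, 1.0]]), kind=TrajectoryKind.GPS_LATLON)
        B = make_traj(np.array([[0.0, 0.0], [1.0, 0.0]]), kind=TrajectoryKind.GPS_LATLON)
        d, _ = dtw_distance(A, B)
        assert d == pytest.approx(1.0)  # only the second pair differs, by 1 degree

    def test_haversine_option(self):
        A = make_traj(np.array([[42.36, -71.06]]), kind=TrajectoryKind.GPS_LATLON)
        B = make_traj(np.array([[42.37, -71.06]]), kind=TrajectoryKind.GPS_LATLON)
        d, _ = dtw_distance(A, B, gps_metric="haversine")
        assert d == pytest.approx(1112.0, rel=0.01)  # 0.01 deg latitude in meters
        with pytest.raises(TypeError):
            dtw_distance(make_traj([1.0]), make_traj([2.0]), gps_metric="haversine")

    def test_empty_rejected(self):
        empty = make_traj([], timestamps=np.empty(0, np.int64))
        with pytest.raises(ValueError):
            dtw_distance(empty, make_traj([1.0]))

    def test_mixed_kinds_rejected(self):
        A = make_traj(np.array([[0.0, 0.0]]), kind=TrajectoryKind.GPS_LATLON)
        with pytest.raises(TypeError):
            dtw_distance(A, make_traj([1.0]))


class TestLCSS:
    def test_full_match(self):
        A = make_traj([1.0, 2.0, 3.0])
        assert lcss_length(A, A, epsilon=0.5) == 3

    def test_exact_matching_example(self):
        z = lcss_length(make_traj([1.0, 2.0, 3.0, 4.0]), make_traj([2.0, 3.0, 5.0]), 0.0)
        assert z == 2

    def test_epsilon_threshold_is_strict(self):
        A, B = make_traj([1.0]), make_traj([1.4])
        assert lcss_length(A, B, epsilon=0.5) == 1
        assert lcss_length(A, B, epsilon=0.3) == 0
        # the comparison is strict: a gap exactly equal to epsilon is no match
        assert lcss_length(make_traj([1.0]), make_traj([1.5]), epsilon=0.5) == 0

    def test_empty_input_zero(self):
        empty = make_traj([], timestamps=np.empty(0, np.int64))
        assert lcss_length(empty, make_traj([1.0]), 0.5) == 0

    @given(lcss_seq, lcss_seq)
    @settings(max_examples=250, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, a, b):
        z = lcss_length(make_traj(a), make_traj(b), epsilon=0.0)
        assert z == brute_force_lcss(tuple(a), tuple(b), 0.0)
        assert 0 <= z <= min(len(a), len(b))

    @given(
        st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=8),
        st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=8),
        st.floats(0.01, 3.0),
        st.floats(0.0, 2.0),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_monotone_in_epsilon(self, a, b, eps, bump):
        A, B = make_traj(a), make_traj(b)
        assert lcss_length(A, B, eps + bump) >= lcss_length(A, B, eps)

    def test_2d_matching_uses_euclidean_norm(self):
        A = make_traj(np.array([[0.0, 0.0]]), kind=TrajectoryKind.GPS_LATLON)
        B = make_traj(np.array([[3.0, 4.0]]), kind=TrajectoryKind.GPS_LATLON)
        assert lcss_length(A, B, epsilon=5.1) == 1
        assert lcss_length(A, B, epsilon=5.0) == 0


class TestLCSSDistance:
    def test_identical_normalized_zero(self):
        A = make_traj([1.0, 2.0, 3.0])
        assert lcss_distance(A, A, epsilon=0.5) == 0.0

    def test_worked_example_both_formulas(self):
        A = make_traj([1.0, 2.0, 3.0, 4.0])
        B = make_traj([2.0, 3.0, 5.0])
        assert lcss_distance(A, B, 0.0) == pytest.approx(3 / 7)
        assert lcss_distance(A, B, 0.0, formula="as_printed") == pytest.approx(11 / 7)

    @given(lcss_seq.filter(len), lcss_seq.filter(len))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_normalized_in_unit_interval(self, a, b):
        d = lcss_distance(make_traj(a), make_traj(b), epsilon=0.5)
        assert 0.0 <= d <= 1.0


class TestLockstep:
    def test_identical_zero(self):
        A = make_traj([1.0, 5.0, 2.0])
        assert lockstep_distance(A, A) == 0.0

    def test_mean_pointwise_example(self):
        d = lockstep_distance(make_traj([0.0, 0.0]), make_traj([3.0, 4.0]))
        assert d == pytest.approx(3.5)

    def test_truncates_to_common_length(self):
        d = lockstep_distance(make_traj([1.0, 2.0, 99.0]), make_traj([2.0, 2.0]))
        assert d == pytest.approx(0.5)  # third point never compared


class TestSimilarityMatrix:
    def test_three_segments_symmetric_zero_diagonal(self):
        g = group_of([make_traj([0.0, 1.0]), make_traj([1.0, 2.0]), make_traj([5.0])])
        m = similarity_matrix(g, "dtw")
        assert m.values.shape == (3, 3)
        np.testing.assert_array_equal(m.values, m.values.T)
        np.testing.assert_array_equal(np.diag(m.values), 0.0)
        assert (m.values[np.triu_indices(3, 1)] >= 0).all()

    def test_identical_segments_all_zero(self):
        t = make_traj([1.0, 2.0, 3.0])
        for metric in ("dtw", "lcss", "lockstep"):
            m = similarity_matrix(group_of([t, t, t]), metric)
            np.testing.assert_array_equal(m.values, 0.0)

    def test_mirror_entries_bit_identical(self, routine_gps_traj):
        from tas.alignment import align

        (group,) = align(routine_gps_traj, "all_days", tau=24.0)
        m = similarity_matrix(group, "dtw")
        assert (m.values == m.values.T).all()

    def test_too_few_segments(self):
        with pytest.raises(ValueError):
            similarity_matrix(group_of([make_traj([1.0])]), "dtw")

    def test_unknown_metric(self):
        g = group_of([make_traj([1.0]), make_traj([2.0])])
        with pytest.raises(ValueError):
            similarity_matrix(g, "frechet")

    def test_incomparable_pair_is_missing_not_zero(self):
        ok = make_traj([1.0, 2.0])
        bad = make_traj(np.array([[1.0, 2.0]]), kind=TrajectoryKind.GPS_LATLON)
        m = similarity_matrix(group_of([ok, ok, bad]), "dtw")
        assert np.isnan(m.values[0, 2]) and np.isnan(m.values[2, 1])
        assert m.values[0, 1] >= 0 and m.n_missing == 2
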