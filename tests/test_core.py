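"""Edge time series, FC, RSS, and frame-subset components."""

import numpy as np
import pytest

from framefilter.core import (
    ConnectivityMatrix,
    FrameSet,
    RegionalTimeSeries,
    component_from_frames,
    edge_index_pairs,
    edge_time_series,
    frame_fc_similarity,
    matrix_to_vec,
    pearson_fc,
    rss_amplitude,
    vec_to_matrix,
    zscore_series,
)


class TestZScore:
    def test_three_point_column_is_exactly_unit(self):
        ts = RegionalTimeSeries(data=np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 4.0]]))
        z = zscore_series(ts)
        np.testing.assert_allclose(z.data[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_raises_naming_node(self):
        ts = RegionalTimeSeries(
            data=np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]),
            node_labels=["a", "flatline"],
        )
        with pytest.raises(ValueError, match="flatline"):
            zscore_series(ts)

    def test_columns_standardized(self, small_ts):
        z = zscore_series(small_ts)
        np.testing.assert_allclose(z.data.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(z.data.std(axis=0, ddof=1), 1, atol=1e-10)


class TestEdgeTimeSeries:
    def test_identical_columns_give_unit_products(self):
        ts = RegionalTimeSeries(data=np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
        ets = edge_time_series(zscore_series(ts))
        np.testing.assert_allclose(ets.data[:, 0], [1.0, 0.0, 1.0])
        assert ets.data[:, 0].sum() / 2 == pytest.approx(1.0)

    def test_anticorrelated_columns(self):
        ts = RegionalTimeSeries(data=np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]))
        ets = edge_time_series(zscore_series(ts))
        np.testing.assert_allclose(ets.data[:, 0], [-1.0, 0.0, -1.0])

    def test_time_mean_identity_many_instances(self):
        # the load-bearing identity: eTS time mean (divisor T-1) == Pearson FC
        rng = np.random.default_rng(0)
        for _ in range(50):
            T = int(rng.integers(5, 40))
            N = int(rng.integers(2, 8))
            ts = RegionalTimeSeries(data=rng.standard_normal((T, N)))
            ets = edge_time_series(zscore_series(ts))
            fc = pearson_fc(ts)
            np.testing.assert_allclose(
                ets.data.sum(axis=0) / (T - 1), fc.vec(), atol=1e-12
            )

    def test_edge_ordering_lexicographic(self):
        pairs = edge_index_pairs(4)
        assert pairs == [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


class TestPearsonFC:
    def test_independent_long_columns_near_zero(self):
        rng = np.random.default_rng(1)
        T = 4000
        ts = RegionalTimeSeries(data=rng.standard_normal((T, 2)))
        fc = pearson_fc(ts)
        assert abs(fc.data[0, 1]) < 3 / np.sqrt(T)

    def test_diagonal_is_one_and_symmetric(self, small_ts):
        fc = pearson_fc(small_ts)
        np.testing.assert_allclose(np.diag(fc.data), 1.0)
        np.testing.assert_allclose(fc.data, fc.data.T, atol=1e-12)


class TestRSS:
    def test_single_edge_abs(self):
        ts = RegionalTimeSeries(data=np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
        ets = edge_time_series(zscore_series(ts))
        np.testing.assert_allclose(rss_amplitude(ets).values, [1.0, 0.0, 1.0])

    def test_hand_arithmetic(self):
        from framefilter.core import EdgeTimeSeries

        ets = EdgeTimeSeries(
            data=np.array([[0.3, -0.4, 1.2]]), edge_index=[(0, 1), (0, 2), (1, 2)]
        )
        expected = np.sqrt(0.09 + 0.16 + 1.44)
        assert rss_amplitude(ets).values[0] == pytest.approx(expected)

    def test_invariant_under_global_sign_flip(self, small_ts):
        z = zscore_series(small_ts)
        ets = edge_time_series(z)
        z.data = -z.data
        ets_flipped = edge_time_series(z)
        np.testing.assert_allclose(
            rss_amplitude(ets).values, rss_amplitude(ets_flipped).values
        )


class TestComponentFromFrames:
    def test_full_frameset_reproduces_fc_exactly(self, small_ts):
        ets = edge_time_series(zscore_series(small_ts))
        fcc = component_from_frames(ets, FrameSet.full(small_ts.n_frames))
        np.testing.assert_allclose(fcc.data, pearson_fc(small_ts).data, atol=1e-12)

    def test_single_frame_returns_that_frame(self, small_ts):
        ets = edge_time_series(zscore_series(small_ts))
        fcc = component_from_frames(ets, FrameSet(indices=[4], T=small_ts.n_frames))
        np.testing.assert_allclose(fcc.vec(), ets.data[4])

    def test_subset_mean(self):
        ts = RegionalTimeSeries(data=np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
        ets = edge_time_series(zscore_series(ts))
        fcc = component_from_frames(ets, FrameSet(indices=[0, 2], T=3))
        assert fcc.vec()[0] == pytest.approx(1.0)

    def test_empty_frameset_rejected(self, small_ts):
        ets = edge_time_series(zscore_series(small_ts))
        with pytest.raises(ValueError):
            component_from_frames(ets, FrameSet(indices=[], T=small_ts.n_frames))


class TestFrameSimilarity:
    def test_scaled_fc_frame_scores_one(self, small_ts):
        ets = edge_time_series(zscore_series(small_ts))
        fc = pearson_fc(small_ts)
        ets.data[0] = 2.5 * fc.vec()
        ets.data[1] = -fc.vec()
        sim = frame_fc_similarity(ets, fc)
        assert sim[0] == pytest.approx(1.0)
        assert sim[1] == pytest.approx(-1.0)

    def test_random_frame_near_zero(self):
        rng = np.random.default_rng(2)
        from framefilter.core import EdgeTimeSeries

        N = 46
        K = N * (N - 1) // 2  # 1035 edges
        ets = EdgeTimeSeries(
            data=rng.standard_normal((20, K)), edge_index=edge_index_pairs(N)
        )
        fc = ConnectivityMatrix(data=vec_to_matrix(rng.standard_normal(K), diag=1.0))
        sim = frame_fc_similarity(ets, fc)
        assert np.all(np.abs(sim) < 0.15)

    def test_zero_variance_frame_warns_and_zeroes(self, small_ts):
        ets = edge_time_series(zscore_series(small_ts))
        ets.data[3] = 0.7  # constant across edges
        with pytest.warns(UserWarning):
            sim = frame_fc_similarity(ets, pearson_fc(small_ts))
        assert sim[3] == 0.0


def test_vectorization_round_trip(rng):
    mat = rng.standard_normal((7, 7))
    mat = (mat + mat.T) / 2
    np.fill_diagonal(mat, 0.0)
    np.testing.assert_allclose(vec_to_matrix(matrix_to_vec(mat)), mat)
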