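"""Graph features: correlations, density, RFSMD, adjacency, efficiency."""


import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topofnirs.data import EpochSet, interleaved_channel_roles
from topofnirs.graph import (
    ConfigError,
    FeatureConfig,
    assemble_features,
    average_efficiency,
    build_adjacency,
    connection_density,
    connection_strength,
    global_efficiency,
    pearson_corr,
    pearson_corr_flagged,
    rfsmd,
)


def floyd_warshall_efficiency(adj: np.ndarray) -> float:
    """Independent brute-force oracle for mean inverse shortest paths."""
    c = adj.shape[0]
    inf = float("inf")
    dist = [[0 if i == j else (1 if adj[i][j] else inf) for j in range(c)]
            for i in range(c)]
    for k in range(c):
        for i in range(c):
            for j in range(c):
                via = dist[i][k] + dist[k][j]
                if via < dist[i][j]:
                    dist[i][j] = via
    total = sum(
        1.0 / dist[i][j]
        for i in range(c)
        for j in range(c)
        if i != j and dist[i][j] < inf
    )
    return total / (c * (c - 1))


class TestPearson:
    def test_identical_series(self):
        assert pearson_corr([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_sign_flip(self):
        assert pearson_corr([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_evaluated_sums(self):
        # cov-sum 4, variance sums 5 and 5 -> 4 / 5
        assert pearson_corr([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_flagged_as_degenerate(self):
        rho, degen = pearson_corr_flagged([1, 1, 1], [1, 2, 3])
        assert rho == 0.0 and degen

    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception):
            pearson_corr([1, 2], [1, 2, 3])


class TestConnectionStrength:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], 0.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.9),
        ],
    )
    def test_normalized_correlation(self, x, y, expected):
        assert connection_strength(x, y) == pytest.approx(expected, abs=1e-12)


class TestConnectionDensity:
    def _cfg(self, window_s):
        return FeatureConfig(window_length_s=window_s)

    def test_perfect_correlation_gives_one(self):
        x = np.arange(10.0)
        assert connection_density(x, 2 * x + 1, self._cfg(0.3), 10.0) == 1.0

    def test_anti_correlation_gives_zero(self):
        x = np.arange(10.0)
        assert connection_density(x, -x, self._cfg(0.3), 10.0) == 0.0

    def test_exhaustive_window_loop_oracle(self):
        # T=6, L=3: windows (1,2,3)/(1,2,3) rho=1, (2,3,4)/(2,3,4) rho=1,
        # then two clearly negative windows -> exactly 2 of 4 exceed 0.3
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([1.0, 2, 3, 4, 2, 0])
        cfg = self._cfg(3.0)
        exceed = 0
        for k in range(4):
            rho = pearson_corr(x[k : k + 3], y[k : k + 3])
            exceed += rho > cfg.density_threshold
        assert exceed == 2
        assert connection_density(x, y, cfg, 1.0) == pytest.approx(0.5)

    def test_full_length_window_is_indicator(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        cfg = self._cfg(2.0)  # 20 samples at 10 Hz = full epoch
        sd = connection_density(x, y, cfg, 10.0)
        assert sd in (0.0, 1.0)
        assert sd == float(pearson_corr(x, y) > cfg.density_threshold)

    def test_too_short_window_rejected(self):
        with pytest.raises(ConfigError):
            connection_density(np.arange(10.0), np.arange(10.0),
                               self._cfg(0.05), 10.0)


class TestRFSMD:
    def test_identical_series_hits_epsilon_ceiling(self):
        x = np.arange(5.0)
        assert rfsmd(x, x, FeatureConfig()) == pytest.approx(1e6)

    def test_constant_unit_difference(self):
        x = np.arange(5.0)
        assert rfsmd(x, x + 1.0, FeatureConfig()) == pytest.approx(
            1.0 / (1.0 + 1e-6)
        )

    def test_hand_computed_mean_difference(self):
        # |1-2| = 1, |2-4| = 2 -> mean 1.5
        assert rfsmd([1.0, 2.0], [2.0, 4.0], FeatureConfig()) == pytest.approx(
            1.0 / (1.5 + 1e-6)
        )


class TestAdjacency:
    def test_identical_channels_complete_graph(self):
        epoch = np.tile(np.arange(10.0), (4, 1))
        adj = build_adjacency(epoch, FeatureConfig())
        expected = 1 - np.eye(4, dtype=int)
        np.testing.assert_array_equal(adj, expected)

    def test_single_edge_from_constructed_vectors(self, rng):
        t = np.arange(30.0)
        a = np.sin(t)
        epoch = np.stack([a, a + 0.01 * rng.normal(size=30),
                          rng.normal(size=30)])
        adj = build_adjacency(epoch, FeatureConfig())
        # verify against direct pairwise evaluation of the correlation rule
        for c1 in range(3):
            for c2 in range(3):
                expected = int(
                    c1 != c2 and pearson_corr(epoch[c1], epoch[c2]) > 0.3
                )
                assert adj[c1, c2] == expected
        assert adj[0, 1] == 1 and adj[0, 2] == 0

    def test_signed_threshold_ignores_anticorrelation(self):
        x = np.arange(10.0)
        adj = build_adjacency(np.stack([x, -x]), FeatureConfig())
        np.testing.assert_array_equal(adj, 0)
        adj_abs = build_adjacency(
            np.stack([x, -x]), FeatureConfig(thresholds_signed=False)
        )
        assert adj_abs[0, 1] == 1


class TestGlobalEfficiency:
    def test_complete_graph(self):
        adj = 1 - np.eye(4, dtype=int)
        assert global_efficiency(adj) == pytest.approx(1.0)

    def test_path_graph_p3(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert global_efficiency(adj) == pytest.approx(5.0 / 6.0)

    def test_empty_graph(self):
        assert global_efficiency(np.zeros((5, 5), dtype=int)) == 0.0

    def test_matches_oracles_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 13))
            adj = (rng.random((n, n)) < 0.3).astype(int)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            ours = global_efficiency(adj)
            assert ours == pytest.approx(floyd_warshall_efficiency(adj), abs=1e-12)
            g = nx.from_numpy_array(adj)
            assert ours == pytest.approx(nx.global_efficiency(g), abs=1e-12)

    def test_asymmetric_rejected(self):
        adj = np.array([[0, 1], [0, 0]])
        with pytest.raises(Exception):
            global_efficiency(adj)


class TestAssembly:
    def test_fused_dimension_arithmetic(self, rng):
        epoch = rng.normal(size=(4, 10))
        rows = np.array([[0, 1], [2, 3]])
        _, _, fused = assemble_features(epoch, rows, FeatureConfig(), 10.0)
        assert fused.f3.shape == (40 + 6 + 1,)

    def test_zero_epoch_degenerates_gracefully(self):
        epoch = np.zeros((4, 10))
        rows = np.array([[0, 1], [2, 3]])
        pair, graph, fused = assemble_features(epoch, rows, FeatureConfig(), 10.0)
        assert pair.degenerate.all()
        assert graph.global_efficiency == 0.0
        np.testing.assert_array_equal(fused.f1, 0.0)

    def test_f3_slices_reproduce_components(self, rng):
        epoch = rng.normal(size=(6, 12))
        rows = np.array([[0, 1], [2, 3], [4, 5]])
        cfg = FeatureConfig()
        pair, graph, fused = assemble_features(epoch, rows, cfg, 10.0)
        f3 = fused.f3
        np.testing.assert_array_equal(f3[:72], epoch.ravel(order="F"))
        # f2 ordering: (s_i, Sd_i, RFSMD_i) per pair
        for i, (ro, rr) in enumerate(rows):
            assert f3[72 + 3 * i] == pytest.approx(
                connection_strength(epoch[ro], epoch[rr])
            )
            assert f3[72 + 3 * i + 1] == pytest.approx(
                connection_density(epoch[ro], epoch[rr], cfg, 10.0)
            )
            assert f3[72 + 3 * i + 2] == pytest.approx(
                rfsmd(epoch[ro], epoch[rr], cfg)
            )
        assert f3[-1] == pytest.approx(graph.global_efficiency)

    def test_scaling_invariance_of_correlation_features(self, rng):
        epoch = rng.normal(size=(4, 15))
        rows = np.array([[0, 1], [2, 3]])
        cfg = FeatureConfig()
        p1, g1, _ = assemble_features(epoch, rows, cfg, 10.0)
        p2, g2, _ = assemble_features(3.7 * epoch, rows, cfg, 10.0)
        np.testing.assert_allclose(p1.strength, p2.strength)
        np.testing.assert_allclose(p1.density, p2.density)
        np.testing.assert_array_equal(g1.adjacency, g2.adjacency)
        assert g1.global_efficiency == g2.global_efficiency
        np.testing.assert_allclose(p1.rfsmd / 3.7, p2.rfsmd, rtol=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_feature_ranges(self, seed):
        rng = np.random.default_rng(seed)
        epoch = rng.normal(size=(4, 10)) * rng.uniform(0.1, 10)
        rows = np.array([[0, 1], [2, 3]])
        pair, graph, _ = assemble_features(epoch, rows, FeatureConfig(), 10.0)
        assert np.all((pair.strength >= 0) & (pair.strength <= 1))
        assert np.all((pair.density >= 0) & (pair.density <= 1))
        assert np.all(pair.rfsmd <= 1e6 + 1e-6)
        assert 0.0 <= graph.global_efficiency <= 1.0


class TestAverageEfficiency:
    def _epoch_set(self, epochs):
        n, c, t = epochs.shape
        return EpochSet(
            epochs=epochs,
            labels=np.zeros(n, dtype=int),
            subject_ids=np.zeros(n, dtype=int),
            sampling_rate=10.0,
            epoch_length_s=t / 10.0,
            channel_roles=interleaved_channel_roles(c // 2),
        )

    def test_complete_graphs_give_hundred_percent(self):
        epochs = np.tile(np.arange(10.0), (3, 4, 1))
        ep = self._epoch_set(epochs)
        assert average_efficiency(ep, FeatureConfig()) == pytest.approx(100.0)

    def test_mean_of_known_efficiencies(self, rng):
        # epoch 0: all channels identical (e = 1); epoch 1: one linked pair
        # among 4 channels (e = 1/6); constructed, then verified componentwise
        base = np.arange(12.0)
        e0 = np.tile(base, (4, 1))
        e1 = rng.normal(size=(4, 12))
        e1[1] = e1[0] + 0.01 * rng.normal(size=12)
        cfg = FeatureConfig()
        effs = [global_efficiency(build_adjacency(e, cfg)) for e in (e0, e1)]
        ep = self._epoch_set(np.stack([e0, e1]))
        assert average_efficiency(ep, cfg) == pytest.approx(100 * np.mean(effs))

    def test_monotone_in_threshold(self, tiny_epoch_set):
        values = [
            average_efficiency(
                tiny_epoch_set, FeatureConfig(adjacency_threshold=thr)
            )
            for thr in (0.1, 0.2, 0.3, 0.4, 0.5)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_empty_set_rejected(self):
        ep = self._epoch_set(np.zeros((0, 4, 10)))
        with pytest.raises(ValueError):
            average_efficiency(ep, FeatureConfig())
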