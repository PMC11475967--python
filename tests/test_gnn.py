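import warnings

import numpy as np
import pytest

from gwtgnn.gnn import (GNNModel, SampleGraph, TrainConfig, build_sample_graph,
                        gnn_forward, mlp_baseline, mlp_forward, predict,
                        train_gnn, train_mlp)


class TestBuildSampleGraph:
    def test_two_training_nodes_single_pair(self):
        g = build_sample_graph(np.array([[0.0], [1.0]]), None, k=1)
        assert sorted(map(tuple, g.edges)) == [(0, 1), (1, 0)]

    def test_saturated_k_gives_complete_train_graph(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.warns(UserWarning, match="clamping"):
            g = build_sample_graph(X, None, k=10)
        assert len(g.edges) == 5 * 4

    def test_collinear_nearest_neighbours(self):
        X = np.array([[0.0], [1.0], [3.0], [7.0]])
        g = build_sample_graph(X, None, k=1)
        undirected = {tuple(sorted(e)) for e in g.edges.tolist()}
        assert undirected == {(0, 1), (1, 2), (2, 3)}

    def test_test_nodes_only_receive(self):
        rng = np.random.default_rng(1)
        g = build_sample_graph(rng.normal(size=(10, 4)),
                               rng.normal(size=(4, 4)), k=3)
        test_set = set(g.test_indices.tolist())
        assert all(src not in test_set for src, _ in g.edges)
        # every test node has at least one incoming edge from a train node
        dsts = {dst for _, dst in g.edges}
        assert test_set <= dsts

    def test_no_self_loops_and_gaussian_weights(self):
        X = np.array([[0.0], [1.0], [2.0]])
        g = build_sample_graph(X, None, k=2, bandwidth=1.0)
        assert all(s != d for s, d in g.edges)
        for (s, d), w in zip(g.edges, g.edge_features[:, 0]):
            dist = abs(X[s, 0] - X[d, 0])
            assert w == pytest.approx(np.exp(-dist ** 2 / 2.0))


class TestForward:
    def test_isolated_node_identity(self):
        """No edges + no layers: the readout sees the raw node feature."""
        graph = SampleGraph(node_features=np.array([[3.25]]),
                            edges=np.empty((0, 2), dtype=int),
                            edge_features=np.empty((0, 1)),
                            train_mask=np.array([True]))
        model = GNNModel(layers=[], readout_W=None, readout_c=None,
                         readout_kind="identity")
        out = gnn_forward(model, graph)
        assert out.data[0, 0] == 3.25

    def test_two_node_hand_computed_forward(self):
        """One layer with hand-set weights vs explicit matrix arithmetic."""
        x0, x1, z = np.array([1.0, -2.0]), np.array([0.5, 0.25]), 0.8
        graph = SampleGraph(node_features=np.vstack([x0, x1]),
                            edges=np.array([[0, 1], [1, 0]]),
                            edge_features=np.array([[z], [z]]),
                            train_mask=np.array([True, True]))
        model = GNNModel.init(in_dim=2, hidden=2, n_layers=1, seed=0)
        W_E = np.array([[0.5, -1.0], [1.0, 0.0], [0.0, 1.0]])
        c_E = np.array([0.1, -0.1])
        W_V = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5], [-0.5, 0.5]])
        c_V = np.array([0.0, 0.2])
        W_R = np.array([[1.0], [-1.0], [2.0], [0.5]])
        c_R = np.array([0.3])
        for name, arr in (("W_E", W_E), ("c_E", c_E), ("W_V", W_V),
                          ("c_V", c_V)):
            model.layers[0][name].data = arr
        model.readout_W.data, model.readout_c.data = W_R, c_R

        # manual forward, written out step by step
        mean_ends = (x0 + x1) / 2.0
        g_new = np.maximum(np.concatenate([[z], mean_ends]) @ W_E + c_E, 0.0)
        h0 = np.maximum(np.concatenate([x0, x1]) @ W_V + c_V, 0.0)  # msg: 1->0
        h1 = np.maximum(np.concatenate([x1, x0]) @ W_V + c_V, 0.0)  # msg: 0->1
        want = np.array([
            np.concatenate([h0, g_new]) @ W_R[:, 0] + c_R[0],
            np.concatenate([h1, g_new]) @ W_R[:, 0] + c_R[0],
        ])
        got = gnn_forward(model, graph).data[:, 0]
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        g = build_sample_graph(X, None, k=3, bandwidth=1.0)
        model = GNNModel.init(in_dim=5, hidden=8, n_layers=2, seed=1)
        base = predict(model, g)
        perm = rng.permutation(12)
        inv = np.argsort(perm)
        g_perm = SampleGraph(node_features=g.node_features[perm],
                             edges=inv[g.edges],
                             edge_features=g.edge_features,
                             train_mask=g.train_mask[perm])
        relabeled = predict(model, g_perm)
        np.testing.assert_allclose(relabeled, base[perm], atol=1e-6)

    def test_neighbour_enumeration_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        g = build_sample_graph(X, None, k=3, bandwidth=1.0)
        model = GNNModel.init(in_dim=3, hidden=8, n_layers=2, seed=2)
        base = predict(model, g)
        shuffle = rng.permutation(len(g.edges))
        g_shuf = SampleGraph(node_features=g.node_features,
                             edges=g.edges[shuffle],
                             edge_features=g.edge_features[shuffle],
                             train_mask=g.train_mask)
        np.testing.assert_allclose(predict(model, g_shuf), base, atol=1e-9)

    def test_test_node_isolation(self):
        """Dropping the test nodes leaves training-node predictions alone."""
        rng = np.random.default_rng(5)
        X_tr, X_te = rng.normal(size=(15, 4)), rng.normal(size=(5, 4))
        full = build_sample_graph(X_tr, X_te, k=4, bandwidth=1.0)
        train_only = build_sample_graph(X_tr, None, k=4, bandwidth=1.0)
        model = GNNModel.init(in_dim=4, hidden=8, n_layers=2, seed=3)
        # identical message multisets; summation order may differ by 1 ulp
        np.testing.assert_allclose(predict(model, full)[:15],
                                   predict(model, train_only), atol=1e-12)


class TestTraining:
    def test_overfit_small_training_set(self):
        rng = np.random.default_rng(0)
        X, y = rng.standard_normal((8, 5)), rng.standard_normal(8)
        g = build_sample_graph(X, None, k=3)
        model, hist = train_gnn(g, y, TrainConfig(epochs=2000, seed=1))
        mae = np.mean(np.abs(predict(model, g)[g.train_indices] - y))
        assert mae < 0.05

    def test_bitwise_reproducible_histories(self):
        rng = np.random.default_rng(1)
        X, y = rng.standard_normal((20, 4)), rng.standard_normal(20)
        runs = []
        for _ in range(2):
            g = build_sample_graph(X, None, k=5)
            _, hist = train_gnn(g, y, TrainConfig(epochs=60, seed=7))
            runs.append(hist)
        assert runs[0] == runs[1]

    def test_loss_decreases_over_training(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 6))
        y = X[:, 0] - 0.5 * X[:, 1] + 0.1 * rng.standard_normal(40)
        for seed in range(5):
            g = build_sample_graph(X, None, k=5)
            _, hist = train_gnn(g, y, TrainConfig(epochs=50, seed=seed,
                                                  early_stop_patience=None))
            assert hist[49] <= hist[0]

    def test_overflowing_activations_raise_with_layer_index(self):
        rng = np.random.default_rng(3)
        X, y = rng.standard_normal((10, 3)) * 1e307, rng.standard_normal(10)
        g = build_sample_graph(X, None, k=3, bandwidth=1.0)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            with pytest.raises(FloatingPointError, match="layer"):
                train_gnn(g, y, TrainConfig(epochs=10, seed=0))

    def test_mismatched_target_length_is_error(self):
        g = build_sample_graph(np.random.default_rng(4).normal(size=(5, 2)),
                               None, k=2)
        with pytest.raises(ValueError, match="length"):
            train_gnn(g, np.zeros(3), TrainConfig(epochs=1))


class TestMLP:
    def test_linear_degenerate_recovers_least_squares(self):
        rng = np.random.default_rng(0)
        w = np.array([1.5, -2.0, 0.5])
        X = rng.standard_normal((60, 3))
        y = X @ w
        cfg = TrainConfig(epochs=3000, learning_rate=0.02, n_layers=0,
                          early_stop_patience=None, seed=0)
        model, _ = train_mlp(X, y, cfg)
        closed_form = np.linalg.lstsq(np.column_stack([X, np.ones(60)]), y,
                                      rcond=None)[0]
        np.testing.assert_allclose(model.weights[0].data[:, 0],
                                   closed_form[:3], atol=1e-2)
        assert abs(model.biases[0].data[0] - closed_form[3]) < 1e-2

    def test_overfit_and_determinism(self):
        rng = np.random.default_rng(1)
        X, y = rng.standard_normal((8, 4)), rng.standard_normal(8)
        cfg = TrainConfig(epochs=2000, seed=2)
        model, hist = train_mlp(X, y, cfg)
        mae = np.mean(np.abs(mlp_forward(model, X).data[:, 0] - y))
        assert mae < 0.05
        _, hist2 = train_mlp(X, y, TrainConfig(epochs=2000, seed=2))
        assert hist == hist2

    def test_baseline_returns_test_predictions(self):
        rng = np.random.default_rng(2)
        X, y = rng.standard_normal((30, 3)), rng.standard_normal(30)
        preds = mlp_baseline(X, y, rng.standard_normal((7, 3)),
                             TrainConfig(epochs=20, seed=0))
        assert preds.shape == (7,)
        assert np.all(np.isfinite(preds))
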