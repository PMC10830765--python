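"""GCN: propagation rule, parameter accounting, gradients, training."""

import numpy as np
import pytest

from morphgcn import (
    BrainGraph,
    GCNClassifier,
    TrainingConfig,
    build_adjacency,
    build_graph,
    gcn_layer_forward,
    normalize_adjacency,
    predict,
    threshold_graph,
    train,
)
from morphgcn.gcn import _ce_loss_and_grad, stack_graphs


def _random_graphs(rng, n_graphs, n_nodes=12, shift=0.0):
    graphs, labels = [], []
    for b in range(n_graphs):
        cls = b % 2
        X = rng.normal(size=(n_nodes, 4))
        X[:, 0] += shift * cls
        graphs.append(build_graph(X, "taxicab", 0.5, scan_id=f"g{b}"))
        labels.append(cls)
    return graphs, labels


class TestNormalizeAdjacency:
    def test_edgeless_graph_maps_to_identity(self):
        G = BrainGraph(n_nodes=4, edge_i=[], edge_j=[], edge_weight=[],
                       tau=0.0, metric="taxicab")
        np.testing.assert_allclose(normalize_adjacency(G), np.eye(4))

    def test_two_nodes_one_unit_edge(self):
        G = BrainGraph(n_nodes=2, edge_i=[0], edge_j=[1], edge_weight=[1.0],
                       tau=0.0, metric="taxicab")
        np.testing.assert_allclose(normalize_adjacency(G), np.full((2, 2), 0.5))

    def test_symmetry_for_random_graphs(self, rng):
        for _ in range(5):
            A = rng.random((9, 9)) * (rng.random((9, 9)) < 0.4)
            A = np.triu(A, 1)
            A = A + A.T
            Ah = normalize_adjacency(A)
            np.testing.assert_allclose(Ah, Ah.T, atol=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            normalize_adjacency(np.array([[0, -1.0], [-1.0, 0]]))


class TestLayerForward:
    def test_zero_input_zero_bias_gives_zero(self, rng):
        H = np.zeros((5, 4))
        A = np.eye(5)
        W = rng.normal(size=(4, 3))
        out = gcn_layer_forward(H, A, W, np.zeros(3))
        np.testing.assert_array_equal(out, 0)

    def test_identity_propagation(self, rng):
        H = rng.normal(size=(6, 4))
        b = rng.normal(size=4)
        out = gcn_layer_forward(H, np.eye(6), np.eye(4), b)
        np.testing.assert_allclose(out, np.maximum(H + b, 0))

    def test_matches_triple_loop_oracle_on_path_graph(self, rng):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1.0
        Ah = normalize_adjacency(A)
        H = rng.normal(size=(3, 4))
        W = rng.normal(size=(4, 2))
        b = rng.normal(size=2)
        expected = np.zeros((3, 2))
        for i in range(3):
            for o in range(2):
                acc = b[o]
                for j in range(3):
                    for k in range(4):
                        acc += Ah[i, j] * H[j, k] * W[k, o]
                expected[i, o] = max(acc, 0.0)
        np.testing.assert_allclose(
            gcn_layer_forward(H, Ah, W, b), expected, atol=1e-10
        )

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape mismatch"):
            gcn_layer_forward(rng.normal(size=(3, 4)), np.eye(2),
                              rng.normal(size=(4, 2)), np.zeros(2))


class TestArchitecture:
    @pytest.mark.parametrize("C,total", [(3, 8835), (2, 8770)])
    def test_parameter_count(self, C, total):
        assert GCNClassifier(n_classes=C).count_parameters() == total

    def test_gcn_stack_without_head_has_8640_parameters(self):
        model = GCNClassifier(n_classes=3)
        assert model.count_parameters(include_head=False) == 8640

    def test_zero_features_zero_biases_give_head_bias_logits(self, rng):
        model = GCNClassifier(n_classes=3, seed=0)
        model.params["bh"] = rng.normal(size=3)
        A = np.eye(6)[None]
        X = np.zeros((1, 6, 4))
        logits = model.forward(A, X)
        np.testing.assert_allclose(logits[0], model.params["bh"])

    def test_node_permutation_invariance(self, rng):
        model = GCNClassifier(n_classes=2, seed=3)
        X = rng.normal(size=(10, 4))
        G = build_graph(X, "mahalanobis", 0.3)
        Ah = normalize_adjacency(G)
        base = model.forward(Ah, X)
        perm = rng.permutation(10)
        P = np.eye(10)[perm]
        np.testing.assert_allclose(
            model.forward(P @ Ah @ P.T, X[perm]), base, atol=1e-9
        )

    def test_eval_forward_is_deterministic(self, rng):
        model = GCNClassifier(n_classes=2, seed=1)
        graphs, _ = _random_graphs(rng, 4)
        A, X = stack_graphs(graphs)
        np.testing.assert_array_equal(model.forward(A, X), model.forward(A, X))

    def test_wrong_feature_dimension_rejected(self, rng):
        model = GCNClassifier(n_classes=2)
        with pytest.raises(ValueError, match="4"):
            model.forward(np.eye(5)[None], rng.normal(size=(1, 5, 3)))

    def test_save_load_round_trip(self, tmp_path, rng):
        model = GCNClassifier(n_classes=3, seed=9)
        model.save(tmp_path / "m.json")
        back = GCNClassifier.load(tmp_path / "m.json")
        graphs, _ = _random_graphs(rng, 3)
        A, X = stack_graphs(graphs)
        np.testing.assert_allclose(back.forward(A, X), model.forward(A, X))


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """Analytic gradients against central differences on a small model."""
        model = GCNClassifier(n_classes=3, hidden=6, dropout=0.0, seed=1)
        A = rng.random((3, 5, 5))
        A = (A + A.transpose(0, 2, 1)) / 2
        X = rng.normal(size=(3, 5, 4))
        y = np.array([0, 1, 2])
        w = np.ones(3)

        def loss():
            cache = {}
            logits = model.forward(A, X, cache=cache)
            val, dlogits = _ce_loss_and_grad(logits, y, w)
            return val, cache, dlogits

        _, cache, dlogits = loss()
        grads = model.backward(cache, dlogits)
        eps = 1e-6
        for k, P in model.params.items():
            flat = P.ravel()
            for idx in np.random.default_rng(2).choice(
                flat.size, size=min(8, flat.size), replace=False
            ):
                old = flat[idx]
                flat[idx] = old + eps
                lp, _, _ = loss()
                flat[idx] = old - eps
                lm, _, _ = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[k].ravel()[idx]
                assert abs(num - ana) < 1e-6 * max(1.0, abs(num)), k


class TestTraining:
    def test_same_seed_reproduces_final_weights(self, rng):
        graphs, labels = _random_graphs(rng, 20, shift=1.0)
        cfg = TrainingConfig(epochs=5, seed=4, val_fraction=0.0)
        runs = []
        for _ in range(2):
            m = GCNClassifier(n_classes=2, seed=4)
            m, _ = train(m, graphs, labels, cfg)
            runs.append(m.get_flat_params())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_separable_toy_reaches_095_train_accuracy(self, rng):
        graphs, labels = _random_graphs(rng, 60, n_nodes=20, shift=3.0)
        m = GCNClassifier(n_classes=2, seed=0)
        m, hist = train(m, graphs, labels,
                        TrainingConfig(epochs=100, val_fraction=0.0))
        assert hist[-1]["train_acc"] >= 0.95

    def test_single_class_training_rejected(self, rng):
        graphs, _ = _random_graphs(rng, 6)
        with pytest.raises(ValueError, match="single class"):
            train(GCNClassifier(n_classes=2), graphs, [0] * 6,
                  TrainingConfig(epochs=1))

    def test_mixed_node_counts_rejected(self, rng):
        g1, _ = _random_graphs(rng, 2, n_nodes=8)
        g2, _ = _random_graphs(rng, 2, n_nodes=9)
        with pytest.raises(ValueError, match="node count"):
            train(GCNClassifier(n_classes=2), g1 + g2, [0, 1, 0, 1],
                  TrainingConfig(epochs=1))

    def test_history_records_validation_when_groups_given(self, rng):
        graphs, labels = _random_graphs(rng, 24, shift=2.0)
        groups = [f"p{i // 2}" for i in range(24)]
        m = GCNClassifier(n_classes=2, seed=0)
        m, hist = train(m, graphs, labels,
                        TrainingConfig(epochs=4, val_fraction=0.3),
                        groups=groups)
        assert all("val_loss" in h for h in hist)


class TestPredict:
    def test_probabilities_normalized_and_consistent(self, rng):
        graphs, labels = _random_graphs(rng, 16, shift=2.0)
        m = GCNClassifier(n_classes=2, seed=0)
        m, _ = train(m, graphs, labels, TrainingConfig(epochs=20, val_fraction=0.0))
        pred, probs = predict(m, graphs)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(pred, probs.argmax(axis=1))

    def test_batch_prediction_equals_per_graph(self, rng):
        graphs, labels = _random_graphs(rng, 8, shift=2.0)
        m = GCNClassifier(n_classes=2, seed=0)
        m, _ = train(m, graphs, labels, TrainingConfig(epochs=10, val_fraction=0.0))
        batch_pred, batch_probs = predict(m, graphs)
        for i, g in enumerate(graphs):
            p1, pr1 = predict(m, [g])
            assert p1[0] == batch_pred[i]
            np.testing.assert_allclose(pr1[0], batch_probs[i], atol=1e-6)
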