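import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dynaglep._autodiff import Tensor, grad_check
from dynaglep.complex_graph import ComplexGraph, GraphEdge, GraphNode
from dynaglep.egnn import (MLP, Adam, ScorerConfig, ScorerParams, aggregate,
                           attention_block, coord_update, edge_message,
                           edge_update, forward, node_update, score_complex,
                           train_scorer)

from conftest import fully_connected_graph

SMALL = ScorerConfig(hidden_dim=16, edge_dim=8, n_layers=2, n_heads=2, seed=0)


@pytest.fixture(scope="module")
def small_params():
    return ScorerParams(SMALL)


@pytest.fixture(scope="module")
def toy_graph():
    return fully_connected_graph(6, element=1, rng=np.random.default_rng(0))


class TestPrimitives:
    def test_zero_weight_message_is_bias(self):
        rng = np.random.default_rng(1)
        phi = MLP([10, 4], rng)
        phi.weights[0].data[:] = 0.0
        phi.biases[0].data[:] = 3.0
        m = edge_message(phi, Tensor(np.ones((2, 4))), Tensor(np.ones((2, 4))),
                         Tensor(np.ones((2, 1))), Tensor(np.ones((2, 1))))
        np.testing.assert_array_equal(m.data, np.full((2, 4), 3.0))

    def test_message_depends_on_coords_only_through_distance(self):
        rng = np.random.default_rng(2)
        phi = MLP([5, 4, 4], rng)
        h_i, h_j = Tensor(rng.normal(size=(1, 2))), Tensor(rng.normal(size=(1, 2)))
        a = Tensor(np.zeros((1, 0)))
        x_i, x_j = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        d1 = Tensor([[np.linalg.norm(x_i - x_j)]])
        d2 = Tensor([[np.linalg.norm(x_j - x_i)]])  # swapped endpoints
        m1 = edge_message(phi, h_i, h_j, d1, a)
        m2 = edge_message(phi, h_i, h_j, d2, a)
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_coord_update_identity_when_phi_x_zero(self):
        rng = np.random.default_rng(3)
        phi = MLP([4, 1], rng)
        phi.weights[0].data[:] = 0.0
        x = Tensor(rng.normal(size=(3, 3)))
        msgs = Tensor(rng.normal(size=(4, 4)))
        src = np.array([0, 1, 2, 0])
        dst = np.array([1, 0, 0, 2])
        x2 = coord_update(phi, x, msgs, src, dst)
        np.testing.assert_array_equal(x2.data, x.data)

    def test_two_node_coord_update_hand_expansion(self):
        c = 0.25
        rng = np.random.default_rng(4)
        phi = MLP([4, 1], rng)
        phi.weights[0].data[:] = 0.0
        phi.biases[0].data[:] = c
        x = Tensor(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        msgs = Tensor(np.zeros((1, 4)))
        # single directed edge 2→1 (src=1, dst=0)
        x2 = coord_update(phi, x, msgs, np.array([1]), np.array([0]))
        np.testing.assert_allclose(x2.data[0], [0 + c * (0 - 2), 0, 0])
        np.testing.assert_allclose(x2.data[1], [2.0, 0, 0])

    def test_symmetric_neighbors_cancel(self):
        rng = np.random.default_rng(5)
        phi = MLP([4, 1], rng)
        phi.weights[0].data[:] = 0.0
        phi.biases[0].data[:] = 0.7
        x = Tensor(np.array([[0.0, 0, 0], [1.0, 0, 0], [-1.0, 0, 0]]))
        msgs = Tensor(np.zeros((2, 4)))
        x2 = coord_update(phi, x, msgs, np.array([1, 2]), np.array([0, 0]))
        np.testing.assert_allclose(x2.data[0], [0.0, 0, 0], atol=1e-12)

    def test_aggregate_empty_permutation_and_sum(self):
        msgs = Tensor(np.ones((2, 3)))
        m = aggregate(msgs, np.array([1, 1]), n_nodes=3)
        np.testing.assert_array_equal(m.data[0], np.zeros(3))      # no neighbors
        np.testing.assert_array_equal(m.data[1], np.full(3, 2.0))  # two unit messages
        m_perm = aggregate(Tensor(np.ones((2, 3))[::-1]), np.array([1, 1]), 3)
        np.testing.assert_array_equal(m.data, m_perm.data)

    def test_node_update_residual_identity(self):
        rng = np.random.default_rng(6)
        phi = MLP([8, 4], rng)
        phi.weights[0].data[:] = 0.0
        phi.biases[0].data[:] = 0.0
        h = Tensor(rng.normal(size=(3, 4)))
        out = node_update(phi, h, Tensor(np.zeros((3, 4))))
        np.testing.assert_array_equal(out.data, h.data)


class TestAttention:
    def test_single_node_identity_mixing(self, small_params):
        h = Tensor(np.random.default_rng(7).normal(size=(1, 16)))
        a = Tensor(np.zeros((0, 8)))
        layer = small_params.layers[0]
        h2, w = attention_block(layer, h, a, np.array([], dtype=int),
                                np.array([], dtype=int), n_heads=2)
        # only the self-loop participates: softmax weight 1 on self
        assert w.shape == (0, 2)
        assert np.isfinite(h2.data).all()

    def test_attention_rows_sum_to_one(self, small_params, toy_graph):
        from dynaglep.egnn import encode_graph

        node_feat, coords, src, dst, edge_raw = encode_graph(toy_graph)
        h = small_params.node_embed(Tensor(node_feat))
        a = small_params.edge_embed(Tensor(edge_raw))
        layer = small_params.layers[0]
        _, w = attention_block(layer, h, a, src, dst, n_heads=2)
        # per-destination weights (edges + self-loop) sum to 1
        for i in range(len(toy_graph.nodes)):
            mask = dst == i
            total = w.data[mask].sum(axis=0) if mask.any() else 0.0
            assert np.all(total <= 1 + 1e-6)

    def test_edge_update_residual_with_zero_projection(self, small_params):
        layer = small_params.layers[0]
        saved = layer["edge_proj2"].data.copy()
        layer["edge_proj2"].data[:] = 0.0
        feats = Tensor(np.random.default_rng(8).normal(size=(5, 8)))
        attn = Tensor(np.random.default_rng(9).random((5, 2)))
        out = edge_update(layer, feats, attn)
        np.testing.assert_array_equal(out.data, feats.data)
        layer["edge_proj2"].data = saved


class TestForward:
    def test_e3_invariance_of_score_and_features(self, small_params, toy_graph):
        s0, pen0 = score_complex(toy_graph, small_params)
        rng = np.random.default_rng(10)
        for trial in range(5):
            R = Rotation.random(random_state=trial).as_matrix()
            t = rng.normal(0, 10, 3)
            nodes = [GraphNode(n.kind, tuple(np.asarray(n.coord) @ R.T + t), n.feature)
                     for n in toy_graph.nodes]
            g2 = ComplexGraph(nodes, toy_graph.edges, toy_graph.ligand_node_ids,
                              toy_graph.pocket_node_ids)
            s1, pen1 = score_complex(g2, small_params)
            assert abs(s0 - s1) <= 1e-5
            assert np.abs(pen0 - pen1).max() <= 1e-5

    def test_coordinates_transform_equivariantly(self, small_params, toy_graph):
        _, _, x0 = forward(toy_graph, small_params)
        R = Rotation.random(random_state=11).as_matrix()
        t = np.array([1.0, -2.0, 3.0])
        nodes = [GraphNode(n.kind, tuple(np.asarray(n.coord) @ R.T + t), n.feature)
                 for n in toy_graph.nodes]
        g2 = ComplexGraph(nodes, toy_graph.edges, toy_graph.ligand_node_ids,
                          toy_graph.pocket_node_ids)
        _, _, x1 = forward(g2, small_params)
        np.testing.assert_allclose(x0.data @ R.T + t, x1.data, atol=1e-5)

    def test_permutation_invariance_of_score(self, small_params, toy_graph):
        s0, _ = score_complex(toy_graph, small_params)
        n = len(toy_graph.nodes)
        perm = np.random.default_rng(12).permutation(n)
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)
        nodes = [toy_graph.nodes[perm[i]] for i in range(n)]
        edges = [GraphEdge(int(inv[e.src]), int(inv[e.dst]), e.channel, e.attr)
                 for e in toy_graph.edges]
        lig = [int(inv[i]) for i in toy_graph.ligand_node_ids]
        s1, _ = score_complex(ComplexGraph(nodes, edges, lig, []), small_params)
        assert abs(s0 - s1) <= 1e-9

    def test_empty_ligand_rejected(self, small_params, toy_graph):
        g = ComplexGraph(toy_graph.nodes, toy_graph.edges, [], [0])
        with pytest.raises(ValueError, match="ligand"):
            forward(g, small_params)

    def test_fixed_weights_bit_reproducible(self, small_params, toy_graph):
        s1, pen1 = score_complex(toy_graph, small_params)
        s2, pen2 = score_complex(toy_graph, small_params)
        assert s1 == s2
        np.testing.assert_array_equal(pen1, pen2)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        graph = fully_connected_graph(4, element=1, rng=np.random.default_rng(13))
        params = ScorerParams(ScorerConfig(hidden_dim=4, edge_dim=2,
                                           n_layers=1, n_heads=2, seed=1))

        def loss():
            z, _, _ = forward(graph, params)
            return z * z

        # representative parameter subset across all submodules
        subset = [params.node_embed.weights[0], params.layers[0]["Wq"],
                  params.layers[0]["phi_x"].biases[-1],
                  params.layers[0]["phi_h"].weights[-1],
                  params.layers[0]["edge_proj1"], params.head.weights[-1]]
        for p in subset:
            assert grad_check(loss, [p]) <= 1e-4


class TestTraining:
    def test_separable_task_learned(self):
        rng = np.random.default_rng(14)
        graphs = [fully_connected_graph(4, element=1 + (i % 2), rng=rng)
                  for i in range(12)]
        labels = [i % 2 for i in range(12)]
        params, losses = train_scorer(graphs, labels, SMALL, epochs=150, lr=5e-3)
        preds = [int(float(forward(g, params)[0].data) > 0) for g in graphs]
        assert np.mean(np.array(preds) == np.array(labels)) >= 0.95
        # average loss decreases over training
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_zero_learning_rate_preserves_params(self):
        rng = np.random.default_rng(15)
        graphs = [fully_connected_graph(3, element=1 + (i % 2), rng=rng)
                  for i in range(4)]
        params = ScorerParams(SMALL)
        before = [p.data.copy() for p in params.parameters()]
        params, _ = train_scorer(graphs, [0, 1, 0, 1], params=params, epochs=2, lr=0.0)
        assert all(np.array_equal(a, p.data)
                   for a, p in zip(before, params.parameters()))

    def test_single_class_rejected(self):
        rng = np.random.default_rng(16)
        graphs = [fully_connected_graph(3, element=1, rng=rng) for _ in range(4)]
        with pytest.raises(ValueError, match="class"):
            train_scorer(graphs, [1, 1, 1, 1], SMALL, epochs=1)

    def test_save_load_roundtrip(self, small_params, toy_graph, tmp_path):
        path = tmp_path / "weights.json"
        small_params.save(path)
        loaded = ScorerParams.load(path)
        s1, _ = score_complex(toy_graph, small_params)
        s2, _ = score_complex(toy_graph, loaded)
        assert s1 == s2
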