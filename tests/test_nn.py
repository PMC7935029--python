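import numpy as np
import pytest

from cgcn.fc_graph import KnnGraph, build_random_graph
from cgcn.nn import CgcnConfig, CgcnModel, EdgeMlp, edgeconv_forward, receptive_field


def naive_edgeconv(x, graph, mlp):
    """Independent oracle: explicit per-node, per-neighbor enumeration."""
    n, f = x.shape
    f_out = mlp.weights[-1].shape[0]
    out = np.empty((n, f_out))
    for i in range(n):
        candidates = []
        for j in graph.neighbors[i]:
            a = np.concatenate([x[i], x[j] - x[i]])
            for w, b in zip(mlp.weights, mlp.biases):
                a = np.maximum(w @ a + b, 0.0)
            candidates.append(a)
        out[i] = np.max(candidates, axis=0)
    return out


def random_mlp(rng, f_in, f_out, depth=1):
    widths = [2 * f_in] + [f_out] * depth
    ws = [rng.standard_normal((widths[m + 1], widths[m])) for m in range(depth)]
    bs = [rng.standard_normal(widths[m + 1]) * 0.1 for m in range(depth)]
    return EdgeMlp(ws, bs)


class TestEdgeConvForward:
    def test_matches_naive_enumeration_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            n = int(rng.integers(3, 21))
            k = int(rng.integers(1, min(6, n)))
            f = int(rng.integers(1, 5))
            graph = build_random_graph(n, k, seed=trial)
            mlp = random_mlp(rng, f, int(rng.integers(1, 6)),
                             depth=int(rng.integers(1, 3)))
            x = rng.standard_normal((n, f))
            got = edgeconv_forward(x, graph, mlp)
            want = naive_edgeconv(x, graph, mlp)
            assert np.abs(got - want).max() < 1e-6

    def test_hand_set_single_unit(self):
        # h(a, b) = ReLU(a + 2b); center 1 with neighbor values {2, 0}
        # candidates: ReLU(1 + 2*(2-1)) = 3 and ReLU(1 + 2*(0-1)) = 0
        graph = KnnGraph(3, 2, np.array([[1, 2], [0, 2], [0, 1]]))
        mlp = EdgeMlp([np.array([[1.0, 2.0]])], [np.zeros(1)])
        x = np.array([[1.0], [2.0], [0.0]])
        out = edgeconv_forward(x, graph, mlp)
        assert out[0, 0] == pytest.approx(3.0)

    def test_identical_neighbors_reduce_to_center_term(self, rng, small_graph):
        f = 3
        mlp = random_mlp(rng, f, 4)
        x = np.tile(rng.standard_normal(f), (5, 1))  # all nodes identical
        out = edgeconv_forward(x, small_graph, mlp)
        w, b = mlp.weights[0], mlp.biases[0]
        expected = np.maximum(w[:, :f] @ x[0] + b, 0.0)
        assert np.allclose(out, expected[None, :].repeat(5, axis=0))

    def test_identity_passthrough_mlp_gives_relu_of_input(self, rng, small_graph):
        f = 2
        w = np.zeros((f, 2 * f))
        w[:, :f] = np.eye(f)
        mlp = EdgeMlp([w], [np.zeros(f)])
        x = rng.standard_normal((5, f))
        out = edgeconv_forward(x, small_graph, mlp)
        assert np.allclose(out, np.maximum(x, 0.0))

    def test_neighbor_order_invariance(self, rng):
        graph = build_random_graph(12, 4, seed=3)
        mlp = random_mlp(rng, 3, 5)
        x = rng.standard_normal((12, 3))
        base = edgeconv_forward(x, graph, mlp)
        shuffled = graph.neighbors.copy()
        for row in shuffled:
            rng.shuffle(row)
        g2 = KnnGraph(12, 4, shuffled)
        assert np.allclose(edgeconv_forward(x, g2, mlp), base)

    def test_width_mismatch_raises(self, rng, small_graph):
        mlp = random_mlp(rng, 3, 4)
        with pytest.raises(ValueError, match="width"):
            edgeconv_forward(rng.standard_normal((5, 2)), small_graph, mlp)


class TestReceptiveField:
    def test_one_layer_is_closed_neighborhood(self, small_graph):
        fields = receptive_field(small_graph, 1)
        for i in range(5):
            assert fields[i] == {i, *small_graph.neighbors[i].tolist()}

    def test_directed_cycle_grows_one_hop_per_layer(self):
        cycle = KnnGraph(5, 1, np.array([[1], [2], [3], [4], [0]]))
        fields = receptive_field(cycle, 2)
        assert all(len(s) == 3 for s in fields)
        assert fields[0] == {0, 1, 2}

    def test_complete_graph_saturates_in_one_layer(self):
        n = 6
        nbrs = np.array([[j for j in range(n) if j != i] for i in range(n)])
        g = KnnGraph(n, n - 1, nbrs)
        assert all(s == set(range(n)) for s in receptive_field(g, 1))


class TestCgcnForward:
    def make_model(self, n, k, seed=0, **kw):
        graph = build_random_graph(n, k, seed=seed)
        cfg = CgcnConfig(n_classes=4, n_conv_layers=3, features_per_layer=(4, 4, 6),
                         **kw)
        return CgcnModel.initialize(cfg, graph, seed=seed, dtype=np.float64), graph

    def test_output_is_probability_vector(self, rng):
        model, _ = self.make_model(10, 3)
        probs = model.forward(rng.standard_normal((7, 10)))
        assert probs.shape == (4,)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_average_pool_of_identical_frames_equals_single_frame(self, rng):
        model, _ = self.make_model(8, 2)
        frame = rng.standard_normal((1, 8))
        clip = np.repeat(frame, 5, axis=0)
        assert np.allclose(model.forward(clip), model.forward(frame), atol=1e-9)

    def test_permuting_nodes_consistently_leaves_probabilities_unchanged(self, rng):
        model, graph = self.make_model(9, 3, seed=5)
        clip = rng.standard_normal((6, 9))
        base = model.forward(clip)
        for _ in range(10):
            perm = rng.permutation(9)
            inv = np.argsort(perm)
            # relabel node i as perm[i] in both the graph and the inputs
            nbrs = perm[graph.neighbors][inv]
            g2 = type(graph)(9, 3, nbrs)
            m2 = CgcnModel(model.config, g2,
                           {k: v.copy() for k, v in model.params.items()},
                           {k: v.copy() for k, v in model.buffers.items()})
            if model.config.node_pool == "flatten":
                # flatten keys the classifier by node label; permute its weights
                w = m2.params["clf.W"].reshape(4, 9, -1)
                m2.params["clf.W"] = w[:, inv].reshape(4, -1).copy()
            out = m2.forward(clip[:, inv])
            assert np.allclose(out, base, atol=1e-8)

    def test_perturbation_locality_follows_receptive_field(self, rng):
        graph = build_random_graph(12, 2, seed=11)
        cfg = CgcnConfig(n_classes=2, n_conv_layers=2, features_per_layer=(3, 3),
                         skip_connections=False, batch_norm=False)
        model = CgcnModel.initialize(cfg, graph, seed=1, dtype=np.float64)
        x = rng.standard_normal((1, 1, 12))
        base, _ = model.forward_batch(x)

        def conv_out(clip):
            h = clip.reshape(1, 12, 1)
            for layer in range(2):
                from cgcn.nn import _edgeconv_batch
                h, _ = _edgeconv_batch(h, graph, model._mlp(layer), False)
            return h[0]

        ref = conv_out(x[0])
        # reverse reachability: u influences i iff u is in i's receptive field
        fields = receptive_field(graph, 2)
        u = 4
        x2 = x.copy()
        x2[0, 0, u] += 1.7
        changed = np.any(np.abs(conv_out(x2[0]) - ref) > 1e-12, axis=1)
        for i in range(12):
            if changed[i]:
                assert u in fields[i]

    def test_recurrent_head_runs_and_normalizes(self, rng):
        model, _ = self.make_model(8, 2, temporal_head="recurrent",
                                   recurrent_hidden=5)
        probs = model.forward(rng.standard_normal((9, 8)))
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_column_count_mismatch_raises(self, rng):
        model, _ = self.make_model(8, 2)
        with pytest.raises(ValueError, match="ROIs"):
            model.forward(rng.standard_normal((5, 9)))


class TestGradients:
    @pytest.mark.parametrize("head,pool,depth", [
        ("average_pool", "flatten", 1),
        ("average_pool", "max", 2),
        ("recurrent", "flatten", 1),
        ("recurrent", "mean", 2),
    ])
    def test_backward_matches_finite_differences(self, head, pool, depth):
        rng = np.random.default_rng(0)
        graph = build_random_graph(7, 3, seed=1)
        cfg = CgcnConfig(n_classes=3, n_conv_layers=3, features_per_layer=(3, 4, 5),
                         temporal_head=head, recurrent_hidden=4, node_pool=pool,
                         mlp_depth=depth)
        model = CgcnModel.initialize(cfg, graph, seed=2, dtype=np.float64)
        # positive biases break exact ReLU/max ties, where the loss is not
        # differentiable and finite differences are meaningless
        for key, val in model.params.items():
            if key.endswith(("beta", ".b")) and val.size:
                model.params[key] = rng.uniform(0.1, 0.5, val.shape)
        x = rng.standard_normal((2, 4, 7))
        y = np.zeros((2, 3))
        y[0, 1] = y[1, 2] = 1

        def loss():
            p, _ = model.forward_batch(x, train=True)
            return -np.mean(np.log(np.sum(p * y, axis=1)))

        probs, cache = model.forward_batch(x, need_cache=True, train=True)
        grads = model.backward_batch(cache, (probs - y) / 2)
        eps = 1e-6
        rng2 = np.random.default_rng(1)
        for name, p in model.params.items():
            flat = p.ravel()
            for i in rng2.choice(flat.size, size=min(5, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                assert abs((lp - lm) / (2 * eps) - grads[name].ravel()[i]) < 1e-6
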