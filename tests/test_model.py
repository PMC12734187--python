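import numpy as np
import pytest

from mdignn.core_io import RunConfig
from mdignn.magnetic_spectral import magnetic_laplacian
from mdignn.mdignn_model import (channel_attention, complex_relu,
                                 conv_layer, forward, init_params,
                                 spatial_attention, unwind)
from mdignn.synthetic_data import SimSpec, simulate_graph
from mdignn.train_eval import forward_graph


@pytest.fixture
def graph():
    return simulate_graph(SimSpec(n_genes=30, n_drivers=4, n_nondrivers=8, seed=2))


@pytest.fixture
def config():
    return RunConfig(num_filters=8, attention_reduction=4, seed=0)


@pytest.fixture
def params(config, rng):
    return init_params(config, 6, rng)


class TestComplexRelu:
    @pytest.mark.parametrize("z,expected", [
        (1 + 2j, 1 + 2j),     # positive real part: kept
        (-1 + 2j, 0),         # negative real part: zeroed
        (0 + 3j, 0 + 3j),     # boundary Re=0: kept
        (-0.5 - 1j, 0),
    ])
    def test_gate_on_real_part(self, z, expected):
        assert complex_relu(np.array([z]))[0] == expected


class TestConvLayer:
    def _simple_params(self, f_in, f_out, wself, wneigh, bias=0.0):
        cfg = RunConfig(num_filters=f_out, num_layers=1,
                        channel_attention=False, spatial_attention=False)
        p = init_params(cfg, f_in, np.random.default_rng(0))
        lp = p.layers[0]
        lp.w_re[0].value[...] = wself.real
        lp.w_im[0].value[...] = wself.imag
        lp.w_re[1].value[...] = wneigh.real
        lp.w_im[1].value[...] = wneigh.imag
        lp.b_re.value[...] = np.real(bias)
        lp.b_im.value[...] = np.imag(bias)
        return p

    def test_zero_operator_reduces_to_dense_layer(self, rng):
        wself = rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))
        wneigh = rng.standard_normal((3, 3)) + 0j
        p = self._simple_params(3, 3, wself, wneigh)
        x = rng.standard_normal((5, 3))
        import scipy.sparse as sp
        out = conv_layer(x, sp.csr_matrix((5, 5), dtype=complex), p, 0)
        np.testing.assert_allclose(out, complex_relu(x @ wself), atol=1e-12)

    def test_identity_configuration(self):
        eye = np.eye(4).astype(complex)
        p = self._simple_params(4, 4, eye, np.zeros((4, 4), dtype=complex))
        x = np.abs(np.random.default_rng(0).standard_normal((6, 4)))
        import scipy.sparse as sp
        out = conv_layer(x, sp.csr_matrix((6, 6), dtype=complex), p, 0)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_two_node_neighbor_only(self, two_node_graph):
        """With Wself=0, Wneigh=I the layer applies L-tilde and the complex
        ReLU keeps pure-imaginary entries (Re = 0 boundary)."""
        op = magnetic_laplacian(two_node_graph, 0.25)
        eye = np.eye(2).astype(complex)
        p = self._simple_params(2, 2, np.zeros((2, 2), complex), eye)
        out = conv_layer(np.eye(2), op.L_shifted, p, 0)
        np.testing.assert_allclose(out, [[0, -1j], [1j, 0]], atol=1e-12)

    def test_shape_mismatch_rejected(self, params):
        with pytest.raises(ValueError, match="width"):
            import scipy.sparse as sp
            conv_layer(np.zeros((4, 99)), sp.csr_matrix((4, 4), dtype=complex),
                       params, 0)


class TestUnwind:
    def test_concatenates_real_and_imaginary(self):
        np.testing.assert_array_equal(unwind(np.array([[1 + 2j]])), [[1.0, 2.0]])

    def test_real_input_pads_zeros(self):
        x = np.arange(6.0).reshape(2, 3)
        out = unwind(x)
        np.testing.assert_array_equal(out[:, 3:], 0)
        assert out.shape == (2, 6)


class TestAttention:
    def test_channel_map_half_at_zero_pool(self, config, params):
        x = np.vstack([np.ones((1, 16)), -np.ones((1, 16))])  # zero column means
        params.att_w1.value[...] = np.eye(16, 4)
        params.att_b1.value[...] = 0
        params.att_w2.value[...] = 0
        params.att_b2.value[...] = 0
        mc, xp = channel_attention(x, params)
        np.testing.assert_allclose(mc, 0.5)
        np.testing.assert_allclose(xp, 0.5 * x)

    def test_spatial_map_half_with_zero_kernel(self, config, params, rng):
        params.conv_w.value[...] = 0
        params.conv_b.value[...] = 0
        x = rng.standard_normal((9, 16))
        ms, xpp = spatial_attention(x, params)
        np.testing.assert_allclose(ms, 0.5)
        np.testing.assert_allclose(xpp, 0.5 * x)
        assert xpp.shape == x.shape

    def test_maps_strictly_inside_unit_interval(self, config, params, rng):
        x = rng.standard_normal((20, 16)) * 10
        mc, xp = channel_attention(x, params)
        ms, _ = spatial_attention(xp, params)
        assert np.all((mc > 0) & (mc < 1))
        assert np.all((ms > 0) & (ms < 1))

    def test_reduction_larger_than_width_rejected(self):
        cfg = RunConfig(num_filters=2, attention_reduction=16)
        with pytest.raises(ValueError, match="smaller r"):
            init_params(cfg, 4, np.random.default_rng(0))


class TestForward:
    def test_zero_head_gives_half_probabilities(self, graph, config, rng):
        params = init_params(config, 6, rng)
        params.head_w.value[...] = 0
        params.head_b.value[...] = 0
        op = magnetic_laplacian(graph, config.q)
        probs = forward(rng.standard_normal((graph.n_nodes, 6)),
                        op.L_shifted, params, config)
        np.testing.assert_allclose(probs, 0.5)

    def test_output_length_and_range(self, graph, config, params, rng):
        op = magnetic_laplacian(graph, config.q)
        probs = forward(rng.standard_normal((graph.n_nodes, 6)),
                        op.L_shifted, params, config)
        assert probs.shape == (graph.n_nodes,)
        assert np.all((probs > 0) & (probs < 1))

    def test_eval_forward_deterministic(self, graph, config, params, rng):
        op = magnetic_laplacian(graph, config.q)
        x = rng.standard_normal((graph.n_nodes, 6))
        np.testing.assert_array_equal(
            forward(x, op.L_shifted, params, config),
            forward(x, op.L_shifted, params, config))

    def test_gcn_mode_keeps_activations_real(self, graph, rng):
        cfg = RunConfig(num_filters=8, gcn_mode=True, attention_reduction=4)
        params = init_params(cfg, 6, rng)
        op = magnetic_laplacian(graph, cfg.q)
        x = rng.standard_normal((graph.n_nodes, 6)).astype(complex)
        for layer in range(len(params.layers)):
            x = conv_layer(x, op.L_shifted, params, layer)
            np.testing.assert_array_equal(x.imag, 0)

    def test_q_zero_complex_pipeline_equals_real_gcn(self, graph, rng):
        """Independent real-arithmetic oracle for the undirected ablation."""
        cfg = RunConfig(num_filters=8, gcn_mode=True, channel_attention=False,
                        spatial_attention=False)
        params = init_params(cfg, 6, rng)
        x = rng.standard_normal((graph.n_nodes, 6))
        op = magnetic_laplacian(graph, 0.0)
        probs = forward(x, op.L_shifted, params, cfg)

        Lt = op.L_shifted.toarray().real
        h = x.copy()
        for lp in params.layers:
            z = h @ lp.w_re[0].value + Lt @ h @ lp.w_re[1].value + lp.b_re.value
            h = z * (z >= 0)
        hu = np.concatenate([h, np.zeros_like(h)], axis=1)
        logits = (hu @ params.head_w.value + params.head_b.value).ravel()
        oracle = 1 / (1 + np.exp(-logits))
        np.testing.assert_allclose(probs, oracle, atol=1e-8)

    def test_permuting_nodes_leaves_channel_attention_invariant(self, config,
                                                                params, rng):
        x = rng.standard_normal((15, 16))
        perm = rng.permutation(15)
        mc, xp = channel_attention(x, params)
        mc_p, xp_p = channel_attention(x[perm], params)
        np.testing.assert_allclose(mc, mc_p, atol=1e-12)
        np.testing.assert_allclose(xp[perm], xp_p, atol=1e-12)


class TestTrainingGraphConsistency:
    def test_autodiff_forward_matches_numpy_forward(self, graph, config, rng):
        params = init_params(config, 6, rng)
        x = rng.standard_normal((graph.n_nodes, 6))
        op = magnetic_laplacian(graph, config.q)
        logits_np = forward(x, op.L_shifted, params, config, return_logits=True)
        logits_ad = forward_graph(x, op, params, config, training=False).value
        np.testing.assert_allclose(logits_ad, logits_np, atol=1e-10)

    def test_gradients_match_finite_differences(self, graph, rng):
        """End-to-end gradient check of the autodiff engine through the
        full model (conv ×2 + both attentions + head + weighted BCE)."""
        from mdignn.train_eval import _weighted_bce

        cfg = RunConfig(num_filters=4, attention_reduction=2, num_layers=2)
        params = init_params(cfg, 3, rng)
        x = rng.standard_normal((graph.n_nodes, 3))
        op = magnetic_laplacian(graph, cfg.q)
        y = (rng.random(graph.n_nodes) < 0.3).astype(float)
        idx = np.arange(graph.n_nodes)

        def loss_value():
            logits = forward_graph(x, op, params, cfg, training=False)
            return _weighted_bce(logits, y, idx, 2.0)

        loss = loss_value()
        loss.backward()
        eps = 1e-6
        rng2 = np.random.default_rng(0)
        for p in params.trainable():
            flat_idx = rng2.integers(0, p.value.size)
            pos = np.unravel_index(flat_idx, p.value.shape)
            orig = p.value[pos]
            p.value[pos] = orig + eps
            up = loss_value().value
            p.value[pos] = orig - eps
            down = loss_value().value
            p.value[pos] = orig
            numeric = (up - down) / (2 * eps)
            analytic = p.grad[pos]
            assert numeric == pytest.approx(analytic, abs=1e-5, rel=1e-4)
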