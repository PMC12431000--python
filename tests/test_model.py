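"""Network components and the composed forward pass."""

import numpy as np
import pytest

from topofnirs.autodiff import Tensor
from topofnirs.model import (
    GraphTemporalNet,
    ModelConfig,
    attention_lstm_cell,
    bilstm_sequence,
    build_pair_sequence,
    cross_entropy,
    graph_attention,
    input_projection,
    pairs_from_epochs,
    temporal_pool,
)


def _zero_lstm_params(in_dim, hidden):
    names = [("Wg", "bf"), ("Wi", "bi"), ("Wc", "bc"), ("Wo", "bo")]
    p = {}
    for w, b in names:
        p[w] = Tensor(np.zeros((in_dim, hidden)))
        p[b] = Tensor(np.zeros(hidden))
    return p


def _random_lstm_params(rng, in_dim, hidden):
    names = [("Wg", "bf"), ("Wi", "bi"), ("Wc", "bc"), ("Wo", "bo")]
    p = {}
    for w, b in names:
        p[w] = Tensor(rng.normal(size=(in_dim, hidden)) * 0.3)
        p[b] = Tensor(rng.normal(size=hidden) * 0.1)
    return p


def lstm_cell_scalar_oracle(h_prev, c_prev, e_i, alpha_i, params):
    """Independent per-element evaluation of the gated update equations."""
    z = np.concatenate([h_prev, e_i, np.atleast_1d(alpha_i)])
    hid = len(h_prev)

    def gate(w, b, fn):
        out = np.empty(hid)
        for j in range(hid):
            acc = b[j]
            for k in range(len(z)):
                acc += z[k] * w[k, j]
            out[j] = fn(acc)
        return out

    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    g = gate(params["Wg"].data, params["bf"].data, sig)
    i = gate(params["Wi"].data, params["bi"].data, sig)
    c_tilde = gate(params["Wc"].data, params["bc"].data, np.tanh)
    c = g * c_prev + i * c_tilde
    o = gate(params["Wo"].data, params["bo"].data, sig)
    return o * np.tanh(c), c


class TestInputProjection:
    def test_zero_input_zero_bias(self):
        wp, bp = Tensor(np.ones((2, 5))), Tensor(np.zeros(5))
        out = input_projection(Tensor(np.zeros((1, 3, 4, 2))), wp, bp)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_selector_matrix_extracts_hbo(self, rng):
        x = rng.normal(size=(2, 3, 6, 2))
        wp = np.zeros((2, 4))
        wp[0, 0] = 1.0  # first output feature = HbO series
        out = input_projection(Tensor(x), Tensor(wp), Tensor(np.zeros(4)))
        np.testing.assert_allclose(out.data[..., 0], x[..., 0])

    def test_matches_explicit_loop_oracle(self, rng):
        x = rng.normal(size=(2, 2, 5, 2))
        wp = rng.normal(size=(2, 3))
        bp = rng.normal(size=3)
        out = input_projection(Tensor(x), Tensor(wp), Tensor(bp)).data
        for b in range(2):
            for p in range(2):
                for t in range(5):
                    expect = x[b, p, t] @ wp + bp
                    np.testing.assert_allclose(out[b, p, t], expect, atol=1e-6)


class TestTransformerEncoder:
    @pytest.fixture
    def model(self, small_model_config):
        return GraphTemporalNet(3, 8, 2 * 3 * 8 + 3 * 3 + 1, small_model_config)

    def test_shape_preserved_and_pairs_shared(self, model, rng):
        x = rng.normal(size=(1, 3, 8, 2))
        x[0, 1] = x[0, 0]  # two identical pairs
        z0 = input_projection(Tensor(x), model.params["Wp"], model.params["bp"])
        z1 = model._encode(z0.reshape(3, 8, model.config.d_model), False, None)
        assert z1.shape == (3, 8, model.config.d_model)
        np.testing.assert_allclose(z1.data[0], z1.data[1], atol=1e-12)
        assert not np.allclose(z1.data[0], z1.data[2])

    def test_attention_rows_are_distributions(self, model, rng):
        x = rng.normal(size=(2, 3, 8, 2))
        z0 = input_projection(Tensor(x), model.params["Wp"], model.params["bp"])
        model._encode(z0.reshape(6, 8, model.config.d_model), False, None)
        attn = model.last_attention
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-9)
        assert (attn >= 0).all()


class TestPoolingAndFusion:
    def test_pool_of_constant_is_constant(self):
        z = np.tile(np.arange(4.0), (2, 5, 1))
        np.testing.assert_allclose(temporal_pool(Tensor(z)).data,
                                   np.tile(np.arange(4.0), (2, 1)))

    def test_pool_mean_of_ramp(self):
        z = np.zeros((1, 3, 2))
        z[0, :, :] = np.array([[1.0], [2.0], [3.0]])
        np.testing.assert_allclose(temporal_pool(Tensor(z)).data, 2.0)

    def test_pool_matches_explicit_sum(self, rng):
        z = rng.normal(size=(2, 7, 3))
        np.testing.assert_allclose(
            temporal_pool(Tensor(z)).data, z.sum(axis=1) / 7, atol=1e-7
        )

    def test_projection_with_zero_weights_returns_bias(self, rng):
        f3 = Tensor(rng.normal(size=(4, 11)))
        ww, bw = Tensor(np.zeros((11, 6))), Tensor(rng.normal(size=6))
        np.testing.assert_allclose((f3 @ ww + bw).data,
                                   np.tile(bw.data, (4, 1)))

    def test_projection_of_basis_vector_selects_column(self, rng):
        ww = rng.normal(size=(11, 6))
        bw = rng.normal(size=6)
        e_j = np.zeros((1, 11))
        e_j[0, 4] = 1.0
        out = (Tensor(e_j) @ Tensor(ww) + Tensor(bw)).data
        np.testing.assert_allclose(out[0], ww[4] + bw)

    def test_pair_sequence_concatenation_identity(self, rng):
        f_t = rng.normal(size=(2, 4, 3))
        f_proj = rng.normal(size=(2, 3))
        e = build_pair_sequence(Tensor(f_t), Tensor(f_proj)).data
        assert e.shape == (2, 4, 6)
        np.testing.assert_array_equal(e[..., :3], f_t)
        for i in range(4):
            np.testing.assert_array_equal(e[:, i, 3:], f_proj)

    def test_pair_sequence_zero_projection(self, rng):
        e = build_pair_sequence(
            Tensor(rng.normal(size=(1, 2, 3))), Tensor(np.zeros((1, 3)))
        ).data
        np.testing.assert_array_equal(e[..., 3:], 0.0)


class TestGraphAttention:
    def test_identical_features_give_uniform_weights(self):
        feats = np.tile([0.5, 0.2, 1.3], (1, 5, 1))
        alpha = graph_attention(Tensor(feats), Tensor(np.ones((3, 1)))).data
        np.testing.assert_allclose(alpha, 0.2, atol=1e-12)

    def test_single_pair_gets_unit_weight(self):
        alpha = graph_attention(
            Tensor(np.ones((1, 1, 3))), Tensor(np.ones((3, 1)))
        ).data
        np.testing.assert_allclose(alpha, [[1.0]])

    def test_log_three_logit_gap_gives_three_to_one_odds(self):
        w = np.array([[1.0], [0.0], [0.0]])
        feats = np.zeros((1, 2, 3))
        feats[0, 1, 0] = np.log(3.0)
        alpha = graph_attention(Tensor(feats), Tensor(w)).data
        np.testing.assert_allclose(alpha, [[0.25, 0.75]], atol=1e-12)

    def test_simplex_for_any_parameters(self, rng):
        feats = rng.normal(size=(3, 6, 3)) * 10
        w = rng.normal(size=(3, 1)) * 5
        alpha = graph_attention(Tensor(feats), Tensor(w)).data
        np.testing.assert_allclose(alpha.sum(axis=-1), 1.0, atol=1e-9)
        assert (alpha > 0).all()


class TestAttentionLSTMCell:
    def test_zero_parameters_zero_cell_state(self):
        p = _zero_lstm_params(4 + 6 + 1, 4)
        h, c = attention_lstm_cell(
            Tensor(np.zeros((1, 4))), Tensor(np.zeros((1, 4))),
            Tensor(np.ones((1, 6))), Tensor(np.ones((1, 1))), p,
        )
        np.testing.assert_allclose(h.data, 0.0)
        np.testing.assert_allclose(c.data, 0.0)

    def test_zero_parameters_nonzero_cell_state(self):
        # gates sit at 0.5, candidate at 0: c = 0.5 * 2 = 1, h = 0.5 tanh(1)
        p = _zero_lstm_params(4 + 6 + 1, 4)
        h, c = attention_lstm_cell(
            Tensor(np.zeros((1, 4))), Tensor(np.full((1, 4), 2.0)),
            Tensor(np.ones((1, 6))), Tensor(np.ones((1, 1))), p,
        )
        np.testing.assert_allclose(c.data, 1.0)
        np.testing.assert_allclose(h.data, 0.5 * np.tanh(1.0), atol=1e-12)
        assert h.data[0, 0] == pytest.approx(0.38080, abs=1e-5)

    def test_matches_scalar_loop_oracle(self, rng):
        hid, ed = 5, 8
        for _ in range(10):
            p = _random_lstm_params(rng, hid + ed + 1, hid)
            h_prev = rng.normal(size=hid)
            c_prev = rng.normal(size=hid)
            e_i = rng.normal(size=ed)
            a_i = rng.uniform()
            h, c = attention_lstm_cell(
                Tensor(h_prev[None]), Tensor(c_prev[None]),
                Tensor(e_i[None]), Tensor(np.array([[a_i]])), p,
            )
            h_ref, c_ref = lstm_cell_scalar_oracle(h_prev, c_prev, e_i, a_i, p)
            np.testing.assert_allclose(h.data[0], h_ref, atol=1e-6)
            np.testing.assert_allclose(c.data[0], c_ref, atol=1e-6)


class TestBiLSTM:
    def test_single_step_with_shared_weights_is_symmetric(self, rng):
        hid, ed = 4, 6
        p = _random_lstm_params(rng, hid + ed + 1, hid)
        e_seq = Tensor(rng.normal(size=(2, 1, ed)))
        alpha = Tensor(np.ones((2, 1)))
        out = bilstm_sequence(e_seq, alpha, p, p, hid).data
        np.testing.assert_allclose(out[:, :hid], out[:, hid:], atol=1e-12)

    def test_zero_parameters_zero_output(self):
        hid, ed = 3, 4
        p = _zero_lstm_params(hid + ed + 1, hid)
        out = bilstm_sequence(
            Tensor(np.ones((1, 5, ed))), Tensor(np.full((1, 5), 0.2)), p, p, hid
        ).data
        np.testing.assert_allclose(out, 0.0)

    def test_reversal_swaps_direction_halves(self, rng):
        hid, ed, cp = 4, 6, 5
        fwd = _random_lstm_params(rng, hid + ed + 1, hid)
        bwd = _random_lstm_params(rng, hid + ed + 1, hid)
        e = rng.normal(size=(2, cp, ed))
        alpha = rng.dirichlet(np.ones(cp), size=2)
        out = bilstm_sequence(Tensor(e), Tensor(alpha), fwd, bwd, hid).data
        out_rev = bilstm_sequence(
            Tensor(e[:, ::-1].copy()), Tensor(alpha[:, ::-1].copy()),
            bwd, fwd, hid,
        ).data
        np.testing.assert_allclose(out[:, :hid], out_rev[:, hid:], atol=1e-10)
        np.testing.assert_allclose(out[:, hid:], out_rev[:, :hid], atol=1e-10)


class TestClassifierAndForward:
    @pytest.fixture
    def setup(self, tiny_inputs, small_model_config):
        model = GraphTemporalNet(
            tiny_inputs.pair_signals.shape[1],
            tiny_inputs.pair_signals.shape[2],
            tiny_inputs.f3.shape[1],
            small_model_config,
            seed=3,
        )
        return model, tiny_inputs

    def test_zero_output_layer_gives_uniform_probabilities(self, setup):
        model, inputs = setup
        model.params["W2"].data[:] = 0.0
        model.params["b2"].data[:] = 0.0
        probs = model.predict_proba(
            inputs.pair_signals[:4], inputs.pair_feats[:4], inputs.f3[:4]
        )
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_probabilities_on_simplex_and_argmax_matches_logits(self, setup):
        model, inputs = setup
        logits = model.forward(
            inputs.pair_signals[:6], inputs.pair_feats[:6], inputs.f3[:6]
        ).data
        probs = model.predict_proba(
            inputs.pair_signals[:6], inputs.pair_feats[:6], inputs.f3[:6]
        )
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-7)
        np.testing.assert_array_equal(
            probs.argmax(axis=1), logits.argmax(axis=1)
        )

    def test_eval_forward_is_deterministic(self, setup):
        model, inputs = setup
        a = model.forward(inputs.pair_signals[:3], inputs.pair_feats[:3],
                          inputs.f3[:3]).data
        b = model.forward(inputs.pair_signals[:3], inputs.pair_feats[:3],
                          inputs.f3[:3]).data
        np.testing.assert_array_equal(a, b)

    def test_batch_equals_stacked_singles(self, setup):
        model, inputs = setup
        batch = model.forward(
            inputs.pair_signals[:8], inputs.pair_feats[:8], inputs.f3[:8]
        ).data
        singles = np.vstack([
            model.forward(
                inputs.pair_signals[i : i + 1],
                inputs.pair_feats[i : i + 1],
                inputs.f3[i : i + 1],
            ).data
            for i in range(8)
        ])
        np.testing.assert_allclose(batch, singles, atol=1e-5)

    def test_all_parameter_groups_receive_gradient(self, setup):
        model, inputs = setup
        logits = model.forward(
            inputs.pair_signals[:6], inputs.pair_feats[:6], inputs.f3[:6]
        )
        loss = cross_entropy(logits, inputs.labels[:6])
        model.zero_grad()
        loss.backward()
        for name, p in model.params.items():
            assert p.grad is not None and np.any(p.grad != 0.0), name

    def test_gradient_finite_difference_spot_check(self, setup):
        model, inputs = setup
        sl = slice(0, 5)

        def loss_value():
            logits = model.forward(
                inputs.pair_signals[sl], inputs.pair_feats[sl], inputs.f3[sl]
            )
            return cross_entropy(logits, inputs.labels[sl])

        loss = loss_value()
        model.zero_grad()
        loss.backward()
        check_rng = np.random.default_rng(0)
        for name in check_rng.choice(sorted(model.params), 3, replace=False):
            p = model.params[name]
            flat = p.data.ravel()
            i = int(check_rng.integers(flat.size))
            eps = 1e-6
            orig = flat[i]
            flat[i] = orig + eps
            up = float(loss_value().data)
            flat[i] = orig - eps
            down = float(loss_value().data)
            flat[i] = orig
            fd = (up - down) / (2 * eps)
            grad = p.grad.ravel()[i]
            assert grad == pytest.approx(fd, rel=1e-3, abs=1e-7), name

    def test_pair_permutation_equivariance_and_lstm_order_sensitivity(
        self, setup, rng
    ):
        model, inputs = setup
        perm = rng.permutation(inputs.pair_signals.shape[1])
        x = inputs.pair_signals[:3]
        pf = inputs.pair_feats[:3]
        f3 = inputs.f3[:3]
        # attention weights permute with the pairs (pre-LSTM equivariance)
        model.forward(x, pf, f3)
        alpha = model.last_alpha.copy()
        model.forward(x[:, perm], pf[:, perm], f3)
        np.testing.assert_allclose(model.last_alpha, alpha[:, perm], atol=1e-10)
        # but the sequence model is order sensitive by design
        out = model.forward(x, pf, f3).data
        out_perm = model.forward(x[:, perm], pf[:, perm], f3).data
        assert not np.allclose(out, out_perm, atol=1e-8)

    def test_alpha_full_vector_mode_runs(self, tiny_inputs):
        cfg = ModelConfig(d_model=8, n_heads=2, ffn_dim=16, lstm_hidden=8,
                          mlp_hidden=16, alpha_mode="full_vector")
        model = GraphTemporalNet(4, 10, tiny_inputs.f3.shape[1], cfg)
        probs = model.predict_proba(
            tiny_inputs.pair_signals[:3], tiny_inputs.pair_feats[:3],
            tiny_inputs.f3[:3],
        )
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-7)

    def test_checkpoint_round_trip(self, setup, tmp_path):
        model, inputs = setup
        before = model.predict_proba(
            inputs.pair_signals[:3], inputs.pair_feats[:3], inputs.f3[:3]
        )
        path = tmp_path / "ckpt.npz"
        model.save(path)
        restored = GraphTemporalNet.load(path)
        after = restored.predict_proba(
            inputs.pair_signals[:3], inputs.pair_feats[:3], inputs.f3[:3]
        )
        np.testing.assert_array_equal(before, after)


def test_pairs_from_epochs_respects_channel_roles(rng):
    epochs = rng.normal(size=(3, 4, 6))
    rows = np.array([[2, 0], [1, 3]])  # scrambled role order
    pairs = pairs_from_epochs(epochs, rows)
    np.testing.assert_array_equal(pairs[:, 0, :, 0], epochs[:, 2, :])
    np.testing.assert_array_equal(pairs[:, 0, :, 1], epochs[:, 0, :])
    np.testing.assert_array_equal(pairs[:, 1, :, 0], epochs[:, 1, :])
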