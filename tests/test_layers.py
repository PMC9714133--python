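"""Feature extractors: LSTM cell, BiLSTM, CNN bank, fusion, attention."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cmedner.autodiff import Tensor
from cmedner.layers import (
    CNNParams,
    ConvKernel,
    FusionParams,
    LSTMParams,
    MHAParams,
    bilstm_encode,
    cnn_encode,
    dropout,
    fuse,
    lstm_step,
    multihead_attention,
)


def scalar_lstm_oracle(x, h, c, pr):
    """Independent scalar evaluation of the gate equations."""
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    f = sig(pr["w_f"] * h + pr["u_f"] * x + pr["b_f"])
    i = sig(pr["w_i"] * h + pr["u_i"] * x + pr["b_i"])
    c_tilde = math.tanh(pr["w_c"] * h + pr["u_c"] * x + pr["b_c"])
    c_new = f * c + i * c_tilde
    o = sig(pr["w_o"] * h + pr["u_o"] * x + pr["b_o"])
    return o * math.tanh(c_new), c_new


class TestLSTMStep:
    def test_zero_parameters_give_zero_state(self):
        p = LSTMParams.zeros(4, 3)
        h, c = lstm_step(np.ones(4), np.zeros(3), np.zeros(3), p)
        np.testing.assert_array_equal(h.data, np.zeros(3))
        np.testing.assert_array_equal(c.data, np.zeros(3))

    def test_saturated_gates_copy_cell_state(self, rng):
        # forget gate saturated open, input gate closed
        p = LSTMParams.zeros(4, 3)
        p.b_f = Tensor(np.full(3, 20.0))
        p.b_i = Tensor(np.full(3, -20.0))
        c_prev = rng.normal(size=3)
        _, c = lstm_step(rng.normal(size=4), rng.normal(size=3), c_prev, p)
        np.testing.assert_allclose(c.data, c_prev, atol=1e-6)

    def test_one_dimensional_step_matches_scalar_oracle(self, rng):
        pr = {k: float(rng.normal()) for k in
              ("w_f", "w_i", "w_c", "w_o", "u_f", "u_i", "u_c", "u_o",
               "b_f", "b_i", "b_c", "b_o")}
        p = LSTMParams(
            *(Tensor(np.array([[pr[f"w_{g}"]]])) for g in "fico"),
            *(Tensor(np.array([[pr[f"u_{g}"]]])) for g in "fico"),
            *(Tensor(np.array([pr[f"b_{g}"]])) for g in "fico"),
            hidden_dim=1,
        )
        x, h0, c0 = float(rng.normal()), float(rng.normal()), float(rng.normal())
        h, c = lstm_step(np.array([x]), np.array([h0]), np.array([c0]), p)
        eh, ec = scalar_lstm_oracle(x, h0, c0, pr)
        assert h.data[0] == pytest.approx(eh, abs=1e-10)
        assert c.data[0] == pytest.approx(ec, abs=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        p = LSTMParams.init(4, 3, rng)
        with pytest.raises(ValueError):
            lstm_step(np.ones(5), np.zeros(3), np.zeros(3), p)


class TestBiLSTM:
    def test_single_position_equals_one_step(self, rng):
        p_f = LSTMParams.init(4, 3, rng)
        p_b = LSTMParams.init(4, 3, rng)
        x = rng.normal(size=(1, 1, 4))
        out = bilstm_encode(x, np.ones((1, 1)), p_f, p_b)
        hf, _ = lstm_step(x[:, 0, :], np.zeros((1, 3)), np.zeros((1, 3)), p_f)
        hb, _ = lstm_step(x[:, 0, :], np.zeros((1, 3)), np.zeros((1, 3)), p_b)
        np.testing.assert_allclose(out.values.data[0, 0, :3], hf.data[0])
        np.testing.assert_allclose(out.values.data[0, 0, 3:], hb.data[0])

    def test_palindrome_symmetry_with_shared_params(self, rng):
        p = LSTMParams.init(4, 3, rng)
        half = rng.normal(size=(3, 4))
        seq = np.concatenate([half, half[::-1]], axis=0)[None]  # palindromic
        out = bilstm_encode(seq, np.ones((1, 6)), p, p).values.data[0]
        fwd, bwd = out[:, :3], out[:, 3:]
        np.testing.assert_allclose(fwd, bwd[::-1], atol=1e-12)

    def test_zero_parameters_give_zero_features(self, rng):
        p = LSTMParams.zeros(4, 3)
        out = bilstm_encode(rng.normal(size=(2, 5, 4)), np.ones((2, 5)), p, p)
        np.testing.assert_array_equal(out.values.data, np.zeros((2, 5, 6)))

    def test_masked_positions_are_zero_and_do_not_leak(self, rng):
        p_f = LSTMParams.init(4, 3, rng)
        p_b = LSTMParams.init(4, 3, rng)
        x = rng.normal(size=(1, 6, 4))
        mask = np.array([[1, 1, 1, 0, 0, 0]], dtype=float)
        out = bilstm_encode(x, mask, p_f, p_b).values.data
        np.testing.assert_array_equal(out[0, 3:], np.zeros((3, 6)))
        # backward pass over only the unmasked prefix == padded run
        short = bilstm_encode(x[:, :3], np.ones((1, 3)), p_f, p_b).values.data
        np.testing.assert_allclose(out[0, :3], short[0], atol=1e-12)


class TestCNN:
    def test_width_one_identity_kernel_reproduces_input(self, rng):
        t = 4
        p = CNNParams([ConvKernel(1, Tensor(np.eye(t)), Tensor(np.zeros(t)))],
                      activation="identity")
        x = rng.normal(size=(2, 5, t))
        out = cnn_encode(x, np.ones((2, 5)), p)
        np.testing.assert_allclose(out.values.data, x, atol=1e-12)

    def test_zero_input_yields_activated_bias(self):
        bias = np.array([0.5, -0.25])
        p = CNNParams([ConvKernel(3, Tensor(np.zeros((9, 2))), Tensor(bias))],
                      activation="relu")
        out = cnn_encode(np.zeros((1, 4, 3)), np.ones((1, 4)), p)
        expected = np.broadcast_to(np.maximum(bias, 0.0), (1, 4, 2))
        np.testing.assert_allclose(out.values.data, expected)

    def test_matches_brute_force_sliding_window(self, rng):
        # 4 positions, 2 channels, kernel widths 1 and 3
        t, n, C = 3, 4, 2
        p = CNNParams.init(t, (1, 3), C, rng)
        x = rng.normal(size=(1, n, t))
        out = cnn_encode(x, np.ones((1, n)), p).values.data[0]
        xp = np.concatenate([np.zeros((1, t)), x[0], np.zeros((1, t))], axis=0)
        expected = np.full((n, C), -np.inf)
        for kern in p.kernels:
            W = kern.weight.data
            for i in range(n):
                if kern.width == 1:
                    window = x[0, i]
                else:
                    window = xp[i : i + 3].ravel()
                y = np.maximum(window @ W + kern.bias.data, 0.0)
                expected[i] = np.maximum(expected[i], y)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_masked_positions_zero(self, rng):
        p = CNNParams.init(3, (3,), 2, rng)
        mask = np.array([[1, 1, 0, 0]], dtype=float)
        out = cnn_encode(rng.normal(size=(1, 4, 3)), mask, p).values.data
        np.testing.assert_array_equal(out[0, 2:], np.zeros((2, 2)))

    def test_even_kernel_width_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            CNNParams.init(3, (2,), 2, rng)

    def test_kernel_too_wide_rejected(self, rng):
        p = CNNParams.init(3, (11,), 2, rng)
        with pytest.raises(ValueError, match="wide"):
            cnn_encode(rng.normal(size=(1, 4, 3)), np.ones((1, 4)), p)


class TestFusion:
    def test_zero_cnn_projection_absorbs_that_path(self, rng):
        p = FusionParams(Tensor(np.eye(3)), Tensor(np.zeros((3, 3))), Tensor(np.zeros(3)))
        vb = rng.normal(size=(1, 4, 3))
        vc = rng.normal(size=(1, 4, 3))
        out = fuse(vb, vc, p)
        np.testing.assert_allclose(out.values.data, vb)
        assert out.stage == "fused"

    def test_identity_projections_sum_elementwise(self, rng):
        p = FusionParams(Tensor(np.eye(3)), Tensor(np.eye(3)), Tensor(np.zeros(3)))
        vb = rng.normal(size=(1, 4, 3))
        vc = rng.normal(size=(1, 4, 3))
        np.testing.assert_allclose(fuse(vb, vc, p).values.data, vb + vc)

    def test_matches_matrix_arithmetic_oracle(self, rng):
        p = FusionParams.init(3, 2, 5, rng)
        vb = rng.normal(size=(2, 4, 3))
        vc = rng.normal(size=(2, 4, 2))
        expected = vb @ p.proj_b.data + vc @ p.proj_c.data + p.bias.data
        np.testing.assert_allclose(fuse(vb, vc, p).values.data, expected, atol=1e-12)

    def test_position_count_mismatch_rejected(self, rng):
        p = FusionParams.init(3, 3, 6, rng)
        with pytest.raises(ValueError, match="position"):
            fuse(rng.normal(size=(1, 4, 3)), rng.normal(size=(1, 5, 3)), p)


def naive_attention_oracle(X, mask, p):
    """Per-head double-loop attention; independent of the layer code."""
    B, n, _ = X.shape
    outs = []
    for b in range(B):
        heads = []
        for i in range(p.h):
            Q = X[b] @ p.w_q[i].data
            K = X[b] @ p.w_k[i].data
            V = X[b] @ p.w_v[i].data
            head = np.zeros_like(Q)
            for q in range(n):
                scores = np.array(
                    [
                        Q[q] @ K[k] / math.sqrt(p.d_k) if mask[b, k] else -np.inf
                        for k in range(n)
                    ]
                )
                w = np.exp(scores - scores.max())
                w = w / w.sum()
                head[q] = w @ V
            heads.append(head)
        outs.append(np.concatenate(heads, axis=1) @ p.w_o.data)
    out = np.stack(outs)
    return out * np.asarray(mask, float)[:, :, None]


class TestMultiheadAttention:
    def test_zero_queries_give_masked_mean_pooling(self, rng):
        p = MHAParams.init(4, 2, rng)
        for i in range(p.h):
            p.w_q[i] = Tensor(np.zeros((4, 2)))
        X = rng.normal(size=(1, 5, 4))
        mask = np.array([[1, 1, 1, 0, 0]], dtype=float)
        out = multihead_attention(X, mask, p).values.data
        pooled = np.concatenate(
            [(X[0, :3] @ p.w_v[i].data).mean(axis=0) for i in range(p.h)]
        )
        expected = pooled @ p.w_o.data
        for pos in range(3):
            np.testing.assert_allclose(out[0, pos], expected, atol=1e-6)

    def test_single_position_is_identity_weight(self, rng):
        p = MHAParams.init(4, 2, rng)
        X = rng.normal(size=(1, 1, 4))
        out, w = multihead_attention(X, np.ones((1, 1)), p, return_weights=True)
        assert w.shape == (1, 2, 1, 1)
        np.testing.assert_allclose(w, 1.0)
        expected = np.concatenate(
            [X[0, 0] @ p.w_v[i].data for i in range(p.h)]
        ) @ p.w_o.data
        np.testing.assert_allclose(out.values.data[0, 0], expected, atol=1e-12)

    def test_matches_naive_double_loop_oracle(self, rng):
        p = MHAParams.init(4, 2, rng)
        X = rng.normal(size=(2, 3, 4))
        mask = np.array([[1, 1, 1], [1, 1, 0]], dtype=float)
        out = multihead_attention(X, mask, p).values.data
        np.testing.assert_allclose(out, naive_attention_oracle(X, mask, p), atol=1e-6)

    def test_attention_rows_are_distributions_over_unmasked_keys(self, rng):
        p = MHAParams.init(6, 3, rng)
        X = rng.normal(size=(2, 5, 6))
        mask = np.array([[1, 1, 1, 1, 0], [1, 1, 0, 0, 0]], dtype=float)
        _, w = multihead_attention(X, mask, p, return_weights=True)
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-8)
        # masked keys get exactly zero weight
        assert w[0, :, :, 4].max() == 0.0
        assert w[1, :, :, 2:].max() == 0.0

    def test_permutation_equivariance(self, rng):
        p = MHAParams.init(4, 2, rng)
        X = rng.normal(size=(1, 5, 4))
        perm = rng.permutation(5)
        out = multihead_attention(X, np.ones((1, 5)), p).values.data
        out_p = multihead_attention(X[:, perm], np.ones((1, 5)), p).values.data
        np.testing.assert_allclose(out_p, out[:, perm], atol=1e-10)

    def test_indivisible_width_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            MHAParams.init(5, 2, rng)


class TestDropout:
    def test_keep_probability_one_is_identity(self, rng):
        x = Tensor(rng.normal(size=(3, 3)))
        assert dropout(x, 1.0, rng) is x

    def test_inverted_scaling_preserves_expectation(self, rng):
        x = Tensor(np.ones((200, 200)))
        out = dropout(x, 0.9, rng).data
        assert out.mean() == pytest.approx(1.0, abs=0.01)
        assert set(np.round(np.unique(out), 6)) <= {0.0, round(1 / 0.9, 6)}
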