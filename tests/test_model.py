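"""Network architecture: shape trace vs the reference stage table,
attention/LSTM unit contracts, residual semantics, variant builds."""

import numpy as np
import pytest

from musemo.model import (
    ArchitectureError,
    AttentionParams,
    LSTMCellParams,
    bilstm_forward,
    build_model,
    default_model_spec,
    lstm_step,
    model_spec_for_input,
    multiplicative_residual,
    self_attention,
    shape_trace,
    softmax_head,
)
from musemo.nn import BiLSTM, Tensor, cross_entropy_logits

# The reference CNN stack's printed output column: (channels, length) per stage.
REFERENCE_TRACE = [
    ("Convolution-1", (32, 256)),
    ("Convolution-2", (32, 126)),
    ("Pool_1", (32, 63)),
    ("BN_1", (32, 63)),
    ("Drop_1", (32, 63)),
    ("Convolution-3", (64, 30)),
    ("Convolution-4", (64, 13)),
    ("Pool_2", (64, 6)),
    ("BN_2", (64, 6)),
    ("Drop_2", (64, 6)),
    ("Convolution-5", (128, 4)),
    ("Convolution-6", (128, 3)),
    ("Pool_3", (128, 2)),
    ("BN_3", (128, 2)),
    ("Drop_3", (128, 2)),
    ("Convolution-7", (64, 2)),
    ("BN_4", (64, 2)),
]


class TestShapeTrace:
    def test_default_spec_reproduces_reference_stack(self):
        assert shape_trace(default_model_spec()) == REFERENCE_TRACE

    def test_too_short_input_names_failing_stage(self):
        spec = default_model_spec()
        spec.input_len = 16
        with pytest.raises(ArchitectureError, match="Convolution"):
            shape_trace(spec)

    def test_scaled_spec_ends_at_length_two(self):
        for n in (8, 16, 24, 32, 128, 256, 384):
            trace = shape_trace(model_spec_for_input(n))
            assert trace[-1][1][1] == 2, n

    def test_tiny_input_rejected(self):
        with pytest.raises(ArchitectureError):
            model_spec_for_input(4)


class TestMultiplicativeResidual:
    def test_scalar_toy_case(self):
        assert multiplicative_residual(2.0, lambda x: 5.0, lambda x: 3.0) == 15.0

    def test_identity_skip_returns_main_path(self, rng):
        f_out = rng.standard_normal((2, 3))
        out = multiplicative_residual(
            np.ones((2, 3)), lambda x: f_out, lambda x: np.ones((2, 3)))
        np.testing.assert_array_equal(out, f_out)

    def test_zero_main_path_annihilates(self, rng):
        x = rng.standard_normal((2, 3))
        out = multiplicative_residual(
            x, lambda x: np.zeros((2, 3)), lambda x: x * 2)
        np.testing.assert_array_equal(out, 0.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ArchitectureError):
            multiplicative_residual(
                np.ones((2, 3)), lambda x: np.ones((2, 3)),
                lambda x: np.ones((2, 4)))


class TestSelfAttention:
    def test_single_position_weight_is_one(self, rng):
        params = AttentionParams(w_q=rng.standard_normal((4, 4)),
                                 w_k=rng.standard_normal((4, 4)),
                                 w_v=rng.standard_normal((4, 4)))
        X = rng.standard_normal((1, 4))
        out, w = self_attention(X, params)
        np.testing.assert_allclose(w, [[1.0]])
        np.testing.assert_allclose(out, X @ params.w_v)

    def test_identical_keys_give_uniform_weights(self, rng):
        # W_k = 0 makes every key identical regardless of X
        params = AttentionParams(w_q=rng.standard_normal((4, 4)),
                                 w_k=np.zeros((4, 4)),
                                 w_v=rng.standard_normal((4, 4)))
        X = rng.standard_normal((5, 4))
        _, w = self_attention(X, params)
        np.testing.assert_allclose(w, 1.0 / 5.0)

    def test_sharp_diagonal_limit(self):
        # Q = K = c*I with large c: softmax saturates to the identity
        c = 10.0
        params = AttentionParams(w_q=c * np.eye(2), w_k=c * np.eye(2),
                                 w_v=np.eye(2))
        X = np.eye(2)
        out, w = self_attention(X, params)
        np.testing.assert_allclose(w, np.eye(2), atol=1e-8)
        np.testing.assert_allclose(out, X, atol=1e-8)

    def test_rows_sum_to_one_randomized(self, rng):
        params = AttentionParams(w_q=rng.standard_normal((6, 3)),
                                 w_k=rng.standard_normal((6, 3)),
                                 w_v=rng.standard_normal((6, 5)))
        for _ in range(100):
            X = rng.standard_normal((4, 6)) * 10
            _, w = self_attention(X, params)
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)


def reference_lstm_step(x_t, h_prev, c_prev, p):
    """Straight-line transcription of the gate equations, kept independent
    of the implementation under test."""
    za = np.concatenate([h_prev, x_t], axis=-1)
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    f_t = sig(za @ p.w_f + p.b_f)
    i_t = sig(za @ p.w_i + p.b_i)
    o_t = sig(za @ p.w_o + p.b_o)
    c_t = f_t * c_prev + i_t * np.tanh(za @ p.w_c + p.b_c)
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


class TestLSTMStep:
    def test_zero_weights_closed_form(self):
        h = np.zeros((1, 3))
        c = np.array([[1.0, -2.0, 0.5]])
        p = LSTMCellParams(*[np.zeros((7, 3))] * 4, *[np.zeros(3)] * 4)
        h_t, c_t = lstm_step(np.ones((1, 4)), h, c, p)
        np.testing.assert_allclose(c_t, 0.5 * c)
        np.testing.assert_allclose(h_t, 0.5 * np.tanh(0.5 * c))

    def test_saturated_forget_gate_preserves_cell(self):
        p = LSTMCellParams(*[np.zeros((7, 3))] * 4,
                           np.full(3, 500.0), np.zeros(3), np.zeros(3),
                           np.zeros(3))
        c = np.array([[0.3, -1.0, 2.0]])
        _, c_t = lstm_step(np.zeros((1, 4)), np.zeros((1, 3)), c, p)
        np.testing.assert_allclose(c_t, c, atol=1e-12)

    def test_matches_independent_transcription(self, rng):
        for _ in range(10):
            p = LSTMCellParams.random(4, 3, rng)
            x = rng.standard_normal((2, 4))
            h = rng.standard_normal((2, 3))
            c = rng.standard_normal((2, 3))
            got_h, got_c = lstm_step(x, h, c, p)
            exp_h, exp_c = reference_lstm_step(x, h, c, p)
            np.testing.assert_allclose(got_h, exp_h, atol=1e-10)
            np.testing.assert_allclose(got_c, exp_c, atol=1e-10)


class TestBiLSTM:
    def test_final_vector_length_from_layer_sizes(self, rng):
        X = rng.standard_normal((3, 5, 16))
        out = bilstm_forward(X, [128, 64, 64], seed=0)
        assert out.shape == (3, 128)  # 2 x last hidden size

    def test_reversed_input_swaps_direction_halves(self, rng):
        """With tied direction weights, reversing the sequence exchanges the
        forward/backward halves of the final state (the directions compute
        mirror-image passes)."""
        h = 6
        module = BiLSTM(4, [h], rng=np.random.default_rng(3))
        for name in ("w_f", "w_i", "w_o", "w_c", "b_f", "b_i", "b_o", "b_c"):
            getattr(module.cells_bwd[0], name).data = \
                getattr(module.cells_fwd[0], name).data.copy()
        X = rng.standard_normal((2, 5, 4))
        fwd = bilstm_forward(X, module=module)
        rev = bilstm_forward(X[:, ::-1, :].copy(), module=module)
        np.testing.assert_allclose(rev[:, :h], fwd[:, h:], atol=1e-12)
        np.testing.assert_allclose(rev[:, h:], fwd[:, :h], atol=1e-12)

    def test_length_one_sequence_is_reversal_invariant(self, rng):
        module = BiLSTM(4, [5, 5], rng=np.random.default_rng(0))
        X = rng.standard_normal((2, 1, 4))
        a = bilstm_forward(X, module=module)
        b = bilstm_forward(X[:, ::-1, :].copy(), module=module)
        np.testing.assert_array_equal(a, b)

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            bilstm_forward(np.empty((2, 0, 4)), [4], seed=0)


class TestSoftmaxHead:
    def test_zero_parameters_give_uniform(self):
        y = softmax_head(np.ones((3, 5)), np.zeros((2, 5)), np.zeros(2))
        np.testing.assert_allclose(y, 0.5)

    def test_extreme_logits_do_not_overflow(self):
        y = softmax_head(np.array([[1.0]]), np.array([[1000.0], [0.0]]),
                         np.zeros(2))
        assert np.all(np.isfinite(y))
        np.testing.assert_allclose(y[0], [1.0, 0.0], atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        y = softmax_head(rng.standard_normal((10, 4)),
                         rng.standard_normal((3, 4)), rng.standard_normal(3))
        np.testing.assert_allclose(y.sum(axis=1), 1.0, atol=1e-12)

    def test_class_permutation_equivariance(self, rng):
        H = rng.standard_normal((4, 5))
        W = rng.standard_normal((3, 5))
        b = rng.standard_normal(3)
        perm = [2, 0, 1]
        np.testing.assert_allclose(softmax_head(H, W, b)[:, perm],
                                   softmax_head(H, W[perm], b[perm]))


class TestBuildModel:
    @pytest.mark.parametrize("variant", ["CSBN", "CNN", "BiLSTM", "CNN-BiLSTM"])
    def test_forward_produces_probabilities(self, variant, rng):
        spec = model_spec_for_input(32, variant=variant)
        model = build_model(spec, seed=0)
        proba = model.predict_proba(rng.standard_normal((5, 32)))
        assert proba.shape == (5, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((proba > 0) & (proba < 1))

    def test_full_size_forward(self, rng):
        model = build_model(default_model_spec(), seed=0)
        proba = model.predict_proba(rng.standard_normal((3, 512)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_ablation_without_attention_has_no_attention_params(self):
        with_attn = build_model(model_spec_for_input(32, "CSBN"), seed=0)
        without = build_model(model_spec_for_input(32, "CNN-BiLSTM"), seed=0)
        assert hasattr(with_attn, "attention")
        assert not hasattr(without, "attention")
        d = with_attn.spec.d_k
        attn_params = 3 * d * d
        assert with_attn.n_parameters() == without.n_parameters() + attn_params

    def test_same_seed_same_parameters(self, rng):
        spec = model_spec_for_input(32)
        a = build_model(spec, seed=9)
        b = build_model(spec, seed=9)
        assert a.n_parameters() == b.n_parameters()
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        X = rng.standard_normal((4, 32))
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_every_parameter_receives_gradient(self, rng):
        """No dead branches: each learnable tensor gets a nonzero gradient."""
        model = build_model(model_spec_for_input(32), seed=2)
        X = rng.standard_normal((8, 32))
        y = np.array([0, 1] * 4)
        loss = cross_entropy_logits(model(Tensor(X)), y)
        loss.backward()
        for p in model.parameters():
            assert p.grad is not None, p.name
            assert np.any(p.grad != 0), p.name

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            model_spec_for_input(32, variant="Transformer")
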