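"""Network layers: closed-form cases, symmetry properties, and the
straight-line forward oracle."""

import numpy as np
import pytest

from jlan.autograd import Tensor
from jlan.model import (
    JlanModel,
    ModelConfig,
    bilstm_encode,
    joint_gate,
    label_attention,
    predict_scores,
    residual_block,
    self_attention,
)
from oracle_forward import straight_line_forward


def tiny_config(**kw):
    defaults = dict(
        L_labels=3, vocab_size=30, e_dim=6, k=2, d=2, mlp_hidden=4,
        conv_kernel=3, dropout=0.0, seed=0,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


def logit(p):
    return float(np.log(p / (1 - p)))


class TestResidualBlock:
    def _zero_F(self, e=3, K=3):
        Wa = Tensor(np.zeros((K, e, e)))
        ba = Tensor(np.zeros(e))
        Wb = Tensor(np.zeros((K, e, e)))
        bb = Tensor(np.zeros(e))
        return Wa, ba, Wb, bb

    def test_identity_on_nonnegative_input(self):
        X = Tensor(np.abs(np.random.default_rng(0).normal(size=(1, 5, 3))))
        out = residual_block(X, *self._zero_F())
        np.testing.assert_array_equal(out.data, X.data)

    def test_relu_clips_negative_input(self):
        X = Tensor(np.array([[[-1.0, 2.0, -3.0]]]))
        out = residual_block(X, *self._zero_F())
        np.testing.assert_array_equal(out.data, [[[0.0, 2.0, 0.0]]])

    def test_one_by_one_kernel_hand_oracle(self):
        # 2 channels, 3 positions, kernel 1: Y = W X + X then ReLU, by hand
        X = np.array([[[1.0, -1.0], [2.0, 0.5], [0.0, 3.0]]])
        W = np.array([[[0.5, 0.0], [1.0, -0.5]]])  # (K=1, in, out)
        Wa = Tensor(W)
        ba = Tensor(np.array([0.1, -0.2]))
        # second conv = identity via unit diagonal, zero bias
        Wb = Tensor(np.eye(2)[None, :, :])
        bb = Tensor(np.zeros(2))
        inner = np.maximum(X[0] @ W[0] + np.array([0.1, -0.2]), 0.0)
        expected = np.maximum(inner @ np.eye(2) + X[0], 0.0)
        out = residual_block(Tensor(X), Wa, ba, Wb, bb)
        np.testing.assert_allclose(out.data[0], expected, atol=1e-12)


class TestBiLstm:
    def _params(self, e=4, k=3, seed=0):
        rng = np.random.default_rng(seed)
        return tuple(
            Tensor(rng.normal(size=s))
            for s in [(e, 4 * k), (k, 4 * k), (4 * k,)]
        )

    def test_single_token_shape(self):
        fwd, bwd = self._params(), self._params(seed=1)
        X = Tensor(np.random.default_rng(2).normal(size=(2, 1, 4)))
        H = bilstm_encode(X, np.ones((2, 1), dtype=bool), fwd, bwd)
        assert H.shape == (2, 1, 6)

    def test_zero_input_zero_bias_fixed_point(self):
        e, k = 4, 3
        zero = tuple(Tensor(np.zeros(s)) for s in [(e, 4 * k), (k, 4 * k), (4 * k,)])
        X = Tensor(np.zeros((1, 5, e)))
        H = bilstm_encode(X, np.ones((1, 5), dtype=bool), zero, zero)
        np.testing.assert_array_equal(H.data, 0.0)

    def test_reversal_swaps_directions(self):
        # shared weights across directions: reversing the tokens mirrors H
        # and swaps its forward/backward halves
        shared = self._params(e=4, k=3, seed=3)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(1, 6, 4))
        mask = np.ones((1, 6), dtype=bool)
        H = bilstm_encode(Tensor(X), mask, shared, shared).data[0]
        H_rev = bilstm_encode(Tensor(X[:, ::-1]), mask, shared, shared).data[0]
        k = 3
        np.testing.assert_allclose(H_rev[::-1, :k], H[:, k:], atol=1e-12)
        np.testing.assert_allclose(H_rev[::-1, k:], H[:, :k], atol=1e-12)

    def test_non_finite_input_rejected(self):
        fwd, bwd = self._params(), self._params(seed=1)
        X = Tensor(np.full((1, 2, 4), np.nan))
        with pytest.raises(ValueError):
            bilstm_encode(X, np.ones((1, 2), dtype=bool), fwd, bwd)

    def test_padding_does_not_leak_into_states(self):
        fwd, bwd = self._params(), self._params(seed=1)
        rng = np.random.default_rng(5)
        X = rng.normal(size=(1, 4, 4))
        H_short = bilstm_encode(
            Tensor(X), np.ones((1, 4), dtype=bool), fwd, bwd
        ).data
        X_pad = np.concatenate([X, rng.normal(size=(1, 3, 4))], axis=1)
        mask = np.array([[1, 1, 1, 1, 0, 0, 0]], dtype=bool)
        H_pad = bilstm_encode(Tensor(X_pad), mask, fwd, bwd).data
        np.testing.assert_allclose(H_pad[:, :4], H_short, atol=1e-12)


class TestSelfAttention:
    def test_zero_w1_gives_uniform_weights(self):
        rng = np.random.default_rng(0)
        H = Tensor(rng.normal(size=(1, 5, 4)))
        W1 = Tensor(np.zeros((3, 2)))
        W2 = Tensor(rng.normal(size=(2, 4)))
        T_S, _ = self_attention(H, np.ones((1, 5), dtype=bool), W1, W2)
        np.testing.assert_allclose(T_S.data, 1 / 5, atol=1e-12)

    def test_single_position(self):
        H = Tensor(np.random.default_rng(1).normal(size=(1, 1, 4)))
        W1 = Tensor(np.random.default_rng(2).normal(size=(3, 2)))
        W2 = Tensor(np.random.default_rng(3).normal(size=(2, 4)))
        T_S, M_S = self_attention(H, np.ones((1, 1), dtype=bool), W1, W2)
        np.testing.assert_allclose(T_S.data, 1.0)
        for j in range(3):
            np.testing.assert_allclose(M_S.data[0, j], H.data[0, 0], atol=1e-12)

    def test_hand_computed_oracle(self):
        # 2 labels, n=3, 2k=2, d=2: full arithmetic by hand with numpy
        H = np.array([[[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]])
        W2 = np.array([[0.5, -0.5], [1.0, 0.5]])
        W1 = np.array([[1.0, 0.0], [-1.0, 2.0]])
        scores = W1 @ np.tanh(W2 @ H[0].T)  # (2, 3)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        T_expected = e / e.sum(axis=1, keepdims=True)
        T_S, M_S = self_attention(
            Tensor(H), np.ones((1, 3), dtype=bool), Tensor(W1), Tensor(W2)
        )
        np.testing.assert_allclose(T_S.data[0], T_expected, atol=1e-9)
        np.testing.assert_allclose(M_S.data[0], T_expected @ H[0], atol=1e-9)


class TestLabelAttention:
    def test_orthogonal_code_gives_uniform_row(self):
        H = np.zeros((1, 4, 2))
        H[0, :, 0] = [1.0, 2.0, -1.0, 0.5]
        C = Tensor(np.array([[0.0, 1.0]]))  # orthogonal to every column
        B_L, _ = label_attention(Tensor(H), np.ones((1, 4), dtype=bool), C)
        np.testing.assert_allclose(B_L.data, 0.25, atol=1e-12)

    def test_matching_column_concentrates(self):
        rng = np.random.default_rng(0)
        Q = np.linalg.qr(rng.normal(size=(4, 4)))[0]  # orthonormal columns
        H = Q[None, :, :]  # 4 positions, 2k=4, mutually orthogonal
        C = Tensor(10.0 * Q[1][None, :])  # aligned with position 1, scale 10
        B_L, _ = label_attention(Tensor(H), np.ones((1, 4), dtype=bool), C)
        assert B_L.data[0, 0, 1] >= 0.9

    def test_single_position_returns_column(self):
        H = Tensor(np.random.default_rng(1).normal(size=(1, 1, 4)))
        C = Tensor(np.random.default_rng(2).normal(size=(3, 4)))
        _, M_L = label_attention(H, np.ones((1, 1), dtype=bool), C)
        for j in range(3):
            np.testing.assert_allclose(M_L.data[0, j], H.data[0, 0], atol=1e-12)

    def test_literal_mode_skips_normalization(self):
        rng = np.random.default_rng(3)
        H = Tensor(rng.normal(size=(1, 4, 4)))
        C = Tensor(rng.normal(size=(2, 4)))
        B_L, _ = label_attention(H, np.ones((1, 4), dtype=bool), C, softmax=False)
        np.testing.assert_allclose(
            B_L.data[0], C.data @ H.data[0].T, atol=1e-12
        )


class TestJointGate:
    def test_zero_weights_give_half_half(self):
        rng = np.random.default_rng(0)
        M_S = Tensor(rng.normal(size=(1, 3, 4)))
        M_L = Tensor(rng.normal(size=(1, 3, 4)))
        alpha, beta, V = joint_gate(M_S, M_L, Tensor(np.zeros(4)), Tensor(np.zeros(4)))
        np.testing.assert_allclose(alpha.data, 0.5)
        np.testing.assert_allclose(beta.data, 0.5)
        np.testing.assert_allclose(V.data[..., :4], 0.5 * M_S.data, atol=1e-12)

    def test_rescaling_when_sum_exceeds_one(self):
        # raw alpha 0.9, beta 0.6 -> rescaled to 0.6, 0.4
        M_S = Tensor(np.array([[[logit(0.9), 0.0]]]))
        M_L = Tensor(np.array([[[logit(0.6), 0.0]]]))
        W = Tensor(np.array([1.0, 0.0]))
        alpha, beta, _ = joint_gate(M_S, M_L, W, W)
        np.testing.assert_allclose(alpha.data, 0.6, atol=1e-12)
        np.testing.assert_allclose(beta.data, 0.4, atol=1e-12)

    def test_sum_below_one_untouched(self):
        M_S = Tensor(np.array([[[logit(0.3), 0.0]]]))
        M_L = Tensor(np.array([[[logit(0.2), 0.0]]]))
        W = Tensor(np.array([1.0, 0.0]))
        alpha, beta, _ = joint_gate(M_S, M_L, W, W)
        np.testing.assert_allclose(alpha.data, 0.3, atol=1e-12)
        np.testing.assert_allclose(beta.data, 0.2, atol=1e-12)


class TestPredictScores:
    def test_zero_mlp_gives_half_probability(self):
        V = Tensor(np.random.default_rng(0).normal(size=(1, 3, 4)))
        zeros = [Tensor(np.zeros(s)) for s in [(4, 2), (2,), (2, 1), (1,)]]
        y_hat, y_tilde = predict_scores(V, *zeros)
        np.testing.assert_array_equal(y_hat.data, 0.0)
        np.testing.assert_allclose(y_tilde.data, 0.5)

    def test_identity_mlp_passes_value_through(self):
        V = Tensor(np.array([[[2.0], [-1.0]]]))  # 2 labels, dim 1
        U1 = Tensor(np.array([[1.0], [0.0]])[:1])  # (1,1)
        params = [Tensor(np.array([[1.0]])), Tensor(np.zeros(1)),
                  Tensor(np.array([[1.0]])), Tensor(np.zeros(1))]
        y_hat, _ = predict_scores(V, *params)
        # ReLU zeroes the negative row before the second layer
        np.testing.assert_allclose(y_hat.data, [[2.0, 0.0]])

    def test_hand_set_two_layer_weights(self):
        V = np.array([[[1.0, -1.0, 0.5, 2.0], [0.0, 1.0, 1.0, -2.0]]])
        rng = np.random.default_rng(4)
        U1, b1 = rng.normal(size=(4, 3)), rng.normal(size=3)
        U2, b2 = rng.normal(size=(3, 2)), rng.normal(size=2)
        expected = (np.maximum(V[0] @ U1 + b1, 0) @ U2 + b2).sum(axis=1)
        y_hat, y_tilde = predict_scores(
            Tensor(V), Tensor(U1), Tensor(b1), Tensor(U2), Tensor(b2)
        )
        np.testing.assert_allclose(y_hat.data[0], expected, atol=1e-9)
        np.testing.assert_allclose(y_tilde.data, 1 / (1 + np.exp(-y_hat.data)))


class TestForward:
    def test_no_residual_stage_still_valid(self):
        model = JlanModel(tiny_config(residual_blocks=0))
        ids = np.array([[3, 4, 5, 6]])
        y_hat, y_tilde, bundle = model.forward(ids)
        assert y_hat.shape == (1, 3)
        assert ((y_tilde.data > 0) & (y_tilde.data < 1)).all()

    def test_deterministic_in_evaluation_mode(self):
        model = JlanModel(tiny_config())
        ids = np.array([[3, 4, 5, 6]])
        a = model.forward(ids, train=False)[0].data
        b = model.forward(ids, train=False)[0].data
        np.testing.assert_array_equal(a, b)

    def test_straight_line_oracle_k2_d2_L3_n4(self):
        model = JlanModel(tiny_config())
        ids = np.array([7, 8, 9, 10])
        y_hat, y_tilde, bundle = model.forward(ids[None, :])
        want = straight_line_forward(model, ids)
        np.testing.assert_allclose(y_hat.data[0], want["y_hat"], atol=1e-6)
        np.testing.assert_allclose(y_tilde.data[0], want["y_tilde"], atol=1e-6)
        np.testing.assert_allclose(bundle.T_S[0], want["T_S"], atol=1e-6)
        np.testing.assert_allclose(bundle.B_L[0], want["B_L"], atol=1e-6)
        np.testing.assert_allclose(bundle.alpha[0], want["alpha"], atol=1e-6)
        np.testing.assert_allclose(bundle.V[0], want["V"], atol=1e-6)

    def test_label_permutation_equivariance(self):
        cfg = tiny_config(L_labels=4)
        model = JlanModel(cfg)
        perm = np.array([2, 0, 3, 1])
        permuted = JlanModel(cfg)
        permuted.load_state_dict(model.state_dict())
        permuted.C.data = model.C.data[perm]
        permuted.W1.data = model.W1.data[perm]
        ids = np.array([[5, 6, 7]])
        base = model.forward(ids)[1].data
        out = permuted.forward(ids)[1].data
        np.testing.assert_allclose(out, base[:, perm], atol=1e-12)

    def test_out_of_vocab_id_rejected(self):
        model = JlanModel(tiny_config(vocab_size=10))
        with pytest.raises(ValueError):
            model.forward(np.array([[11]]))

    @pytest.mark.parametrize("mode", ["label_only", "self_only", "no_joint"])
    def test_ablation_modes_produce_scores(self, mode):
        model = JlanModel(tiny_config(ablation=mode))
        y_hat, _, bundle = model.forward(np.array([[3, 4, 5]]))
        assert y_hat.shape == (1, 3)
        if mode == "label_only":
            assert bundle.T_S is None
        if mode == "self_only":
            assert bundle.B_L is None

    def test_attention_rows_normalized_with_padding(self):
        model = JlanModel(tiny_config())
        ids = np.array([[3, 4, 5, 0, 0], [6, 7, 8, 9, 10]])
        _, _, bundle = model.forward(ids)
        np.testing.assert_allclose(bundle.T_S.sum(-1), 1.0, atol=1e-6)
        np.testing.assert_allclose(bundle.B_L.sum(-1), 1.0, atol=1e-6)
        assert (bundle.T_S[0, :, 3:] == 0).all()
        assert (bundle.B_L[0, :, 3:] == 0).all()


class TestExportAttention:
    def _setup(self):
        from jlan.corpus import EncodedDocument, Vocabulary

        vocab = Vocabulary({"<pad>": 0, "<unk>": 1, "cough": 2, "fever": 3})
        model = JlanModel(tiny_config(vocab_size=4))
        label_index = {"011": 0, "012": 1, "013": 2}
        doc = EncodedDocument("d1", np.array([2, 3, 2]), np.array([1, 0, 0]))
        return model, vocab, label_index, doc

    def test_weights_sum_to_one(self):
        model, vocab, li, doc = self._setup()
        rows = model.export_attention(doc, vocab, "012", li)
        assert len(rows) == 3
        assert sum(r["self_attn"] for r in rows) == pytest.approx(1.0, abs=1e-6)
        assert sum(r["label_attn"] for r in rows) == pytest.approx(1.0, abs=1e-6)
        assert rows[0]["token"] == "cough"

    def test_single_token_gets_full_weight(self):
        from jlan.corpus import EncodedDocument

        model, vocab, li, _ = self._setup()
        doc = EncodedDocument("d2", np.array([3]), np.array([0, 1, 0]))
        rows = model.export_attention(doc, vocab, "011", li)
        assert rows[0]["self_attn"] == pytest.approx(1.0)
        assert rows[0]["label_attn"] == pytest.approx(1.0)

    def test_unknown_code_rejected(self):
        model, vocab, li, doc = self._setup()
        with pytest.raises(KeyError):
            model.export_attention(doc, vocab, "999", li)
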