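"""The JLAN network: embedding -> residual convolution -> Bi-LSTM -> dual
attention (self + label) -> joint gate -> per-label scores.

Shapes follow the structured-self-attention convention: for a batch of B
documents of (padded) length n over L labels,

* hidden states  H      : (B, n, 2k)   -- Bi-LSTM forward/backward concat
* self-attention T_S    : (B, L, n)    -- row-softmax of W1 tanh(W2 H)
* label attention B_L   : (B, L, n)    -- row-softmax of C H
* per-label views M_S, M_L : (B, L, 2k)
* gates alpha, beta     : (B, L), constrained to 0 < alpha + beta <= 1
* joint representation V: (B, L, 4k) = [alpha*M_S ; beta*M_L]

Scores are sum-pooled over the output of a shared two-layer MLP applied per
label row, then squashed with a sigmoid.  PAD positions carry exactly zero
attention weight; the attention matrices are retained per batch in an
:class:`AttentionBundle` for interpretability export.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .corpus import (
    PAD_ID,
    CodeDescription,
    EncodedDocument,
    Vocabulary,
)

ABLATION_MODES = ("full", "label_only", "self_only", "no_joint")


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Defaults for ``e_dim``, ``d`` and ``residual_blocks`` follow the reference
    configuration (embedding 256, attention inner dimension 200, one residual
    block); ``k`` is the per-direction LSTM hidden size.
    """

    L_labels: int
    vocab_size: int
    e_dim: int = 256
    k: int = 256
    d: int = 200
    residual_blocks: int = 1
    conv_kernel: int = 3
    mlp_hidden: int = 512
    mlp_out: int = 1
    dropout: float = 0.2
    seed: int = 0
    label_attention_softmax: bool = True
    use_bilstm: bool = True
    ablation: str = "full"

    def __post_init__(self):
        if self.ablation not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {self.ablation!r}")
        for name in ("L_labels", "vocab_size", "e_dim", "k", "d", "mlp_hidden", "mlp_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.residual_blocks < 0:
            raise ValueError("residual_blocks must be >= 0")


@dataclass
class AttentionBundle:
    """Interpretability surface of one forward pass (numpy copies)."""

    T_S: np.ndarray | None  # (B, L, n)
    B_L: np.ndarray | None  # (B, L, n)
    M_S: np.ndarray | None  # (B, L, 2k)
    M_L: np.ndarray | None  # (B, L, 2k)
    alpha: np.ndarray | None  # (B, L)
    beta: np.ndarray | None  # (B, L)
    V: np.ndarray  # (B, L, joint_dim)


# ---------------------------------------------------------------------------
# functional layers (operate on autograd Tensors)


def conv1d_same(X: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Same-padded 1-D convolution along the token axis.

    ``X`` is (B, n, c_in); ``W`` is (K, c_in, c_out).  Implemented as a sum of
    shifted matmuls over the kernel taps.
    """
    K = W.shape[0]
    n = X.shape[1]
    if K > n + K - 1:  # unreachable for K >= 1; guard for clarity
        raise ValueError("kernel wider than padded sequence")
    left = (K - 1) // 2
    Xp = ag.pad_axis(X, axis=1, before=left, after=K - 1 - left)
    out = None
    for j in range(K):
        term = Xp[:, j : j + n, :] @ W[j]
        out = term if out is None else out + term
    return out + b


def residual_block(X: Tensor, Wa: Tensor, ba: Tensor, Wb: Tensor, bb: Tensor) -> Tensor:
    """ReLU(F(X) + X) with F = conv -> ReLU -> conv and identity shortcut."""
    F = conv1d_same(ag.relu(conv1d_same(X, Wa, ba)), Wb, bb)
    return ag.relu(F + X)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _lstm_direction(
    X: Tensor, mask: np.ndarray, Wx: Tensor, Wh: Tensor, b: Tensor, reverse: bool
) -> Tensor:
    """One LSTM direction over (B, n, e); returns hidden states (B, n, k).

    A fused op: the time loop runs in plain NumPy and a single hand-written
    backward closure backpropagates through the whole recurrence, which keeps
    graph overhead off the critical path.  PAD steps (mask 0) leave the state
    untouched, so padding never leaks into the recurrence.  Gate order in the
    stacked weight matrices is i, f, g, o.
    """
    B, n, _ = X.shape
    k = Wh.shape[0]
    m_all = mask.astype(np.float64)[:, :, None]  # (B, n, 1)
    order = list(range(n - 1, -1, -1) if reverse else range(n))

    h = np.zeros((B, k))
    c = np.zeros((B, k))
    H = np.empty((B, n, k))
    cache: dict[int, tuple] = {}
    for t in order:
        m = m_all[:, t]
        z = X.data[:, t, :] @ Wx.data + h @ Wh.data + b.data
        i = _sigmoid(z[:, :k])
        f = _sigmoid(z[:, k : 2 * k])
        g = np.tanh(z[:, 2 * k : 3 * k])
        o = _sigmoid(z[:, 3 * k :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache[t] = (i, f, g, o, tc, h, c, m)
        c = c_new * m + c * (1.0 - m)
        h = h_new * m + h * (1.0 - m)
        H[:, t, :] = h

    out = Tensor(H, parents=(X, Wx, Wh, b))

    def bwd(grad: np.ndarray) -> None:
        dX = np.zeros_like(X.data) if X.requires_grad else None
        dWx = np.zeros_like(Wx.data)
        dWh = np.zeros_like(Wh.data)
        db = np.zeros_like(b.data)
        dh = np.zeros((B, k))
        dc = np.zeros((B, k))
        for t in reversed(order):
            i, f, g, o, tc, h_prev, c_prev, m = cache[t]
            dh = dh + grad[:, t, :]
            dh_new = dh * m
            dc_new = dc * m
            dc_carry = dc * (1.0 - m)
            dh_carry = dh * (1.0 - m)
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
            df = dc_new * c_prev
            di = dc_new * g
            dg = dc_new * i
            dc = dc_carry + dc_new * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            if dX is not None:
                dX[:, t, :] = dz @ Wx.data.T
            dWx += X.data[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dh_carry + dz @ Wh.data.T
        if X.requires_grad:
            X._accumulate(dX)
        if Wx.requires_grad:
            Wx._accumulate(dWx)
        if Wh.requires_grad:
            Wh._accumulate(dWh)
        if b.requires_grad:
            b._accumulate(db)

    out._backward = bwd
    return out


def bilstm_encode(
    X: Tensor, mask: np.ndarray, fwd: Sequence[Tensor], bwd: Sequence[Tensor]
) -> Tensor:
    """Bidirectional LSTM; returns H of shape (B, n, 2k).

    Column d of H (per document) concatenates the forward hidden state at
    step d with the backward hidden state at step d.
    """
    if not np.isfinite(X.data).all():
        raise ValueError("non-finite input to bilstm_encode")
    Hf = _lstm_direction(X, mask, *fwd, reverse=False)
    Hb = _lstm_direction(X, mask, *bwd, reverse=True)
    return ag.concat([Hf, Hb], axis=-1)


def self_attention(
    H: Tensor, mask: np.ndarray, W1: Tensor, W2: Tensor
) -> tuple[Tensor, Tensor]:
    """Structured self-attention: T_S = softmax(W1 tanh(W2 H)), M_S = T_S H."""
    t = ag.tanh(H @ W2.transpose())  # (B, n, d)
    logits = (t @ W1.transpose()).transpose(0, 2, 1)  # (B, L, n)
    T_S = ag.masked_softmax(logits, mask[:, None, :], axis=-1)
    M_S = T_S @ H
    return T_S, M_S


def label_attention(
    H: Tensor, mask: np.ndarray, C: Tensor, softmax: bool = True
) -> tuple[Tensor, Tensor]:
    """Label-wise attention scored by the trainable code matrix C.

    Raw scores are the dot products C H between each code embedding and each
    hidden state.  With ``softmax`` (default) the scores are normalized over
    token positions like the self-attention rows; without it the literal
    unnormalized combination is used (PAD positions zeroed).
    """
    logits = (H @ C.transpose()).transpose(0, 2, 1)  # (B, L, n)
    if softmax:
        B_L = ag.masked_softmax(logits, mask[:, None, :], axis=-1)
    else:
        B_L = logits * mask[:, None, :].astype(np.float64)
    M_L = B_L @ H
    return B_L, M_L


def joint_gate(
    M_S: Tensor, M_L: Tensor, W3: Tensor, W4: Tensor
) -> tuple[Tensor, Tensor, Tensor]:
    """Per-label gates alpha, beta and the joint representation V.

    alpha = sigmoid(M_S W3), beta = sigmoid(M_L W4); when alpha+beta exceeds 1
    both are rescaled by 1/(alpha+beta) so that 0 < alpha+beta <= 1 always
    holds (minimal intervention: sums already within the bound are untouched).
    """
    a = ag.sigmoid(M_S @ W3)  # (B, L)
    b = ag.sigmoid(M_L @ W4)
    denom = ag.maximum_const(a + b, 1.0)
    alpha = a / denom
    beta = b / denom
    B, L = alpha.shape
    V = ag.concat(
        [alpha.reshape(B, L, 1) * M_S, beta.reshape(B, L, 1) * M_L], axis=-1
    )
    return alpha, beta, V


def predict_scores(
    V: Tensor, U1: Tensor, b1: Tensor, U2: Tensor, b2: Tensor
) -> tuple[Tensor, Tensor]:
    """Shared two-layer MLP per label row, sum-pooled, then sigmoid."""
    Z = ag.relu(V @ U1 + b1) @ U2 + b2  # (B, L, m)
    y_hat = Z.sum(axis=-1)
    return y_hat, ag.sigmoid(y_hat)


# ---------------------------------------------------------------------------


class JlanModel:
    """Parameter container plus the forward pass.

    Parameters are float64 tensors initialized from a seeded generator
    (Glorot-style scales).  ``ablation`` selects which document representation
    feeds the output MLP: the gated concatenation (full), one attention branch
    alone, or the ungated sum of both branches.
    """

    def __init__(self, config: ModelConfig, embeddings: np.ndarray | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        two_k = 2 * c.k

        def glorot(*shape):
            fan_in = shape[0] if len(shape) == 1 else int(np.prod(shape[:-1]))
            return Tensor(
                rng.normal(0.0, 1.0 / np.sqrt(max(fan_in, 1)), size=shape),
                requires_grad=True,
            )

        if embeddings is not None:
            E = np.array(embeddings, dtype=np.float64)
            if E.shape != (c.vocab_size, c.e_dim):
                raise ValueError("embedding matrix shape mismatch")
        else:
            E = rng.normal(0.0, 0.1, size=(c.vocab_size, c.e_dim))
        E[PAD_ID] = 0.0
        self.E = Tensor(E, requires_grad=True)

        self.res_params = [
            (
                glorot(c.conv_kernel, c.e_dim, c.e_dim),
                Tensor(np.zeros(c.e_dim), requires_grad=True),
                glorot(c.conv_kernel, c.e_dim, c.e_dim),
                Tensor(np.zeros(c.e_dim), requires_grad=True),
            )
            for _ in range(c.residual_blocks)
        ]
        if c.use_bilstm:
            self.lstm_fwd = (
                glorot(c.e_dim, 4 * c.k),
                glorot(c.k, 4 * c.k),
                Tensor(np.zeros(4 * c.k), requires_grad=True),
            )
            self.lstm_bwd = (
                glorot(c.e_dim, 4 * c.k),
                glorot(c.k, 4 * c.k),
                Tensor(np.zeros(4 * c.k), requires_grad=True),
            )
            self.W_proj = None
        else:
            # bypass flag: a learned linear map stands in for the recurrence
            self.lstm_fwd = self.lstm_bwd = None
            self.W_proj = glorot(c.e_dim, two_k)

        self.W2 = glorot(c.d, two_k)
        self.W1 = glorot(c.L_labels, c.d)
        self.C = glorot(c.L_labels, two_k)
        self.W3 = glorot(two_k)
        self.W4 = glorot(two_k)

        in_dim = 4 * c.k if c.ablation == "full" else two_k
        self.U1 = glorot(in_dim, c.mlp_hidden)
        self.b1 = Tensor(np.zeros(c.mlp_hidden), requires_grad=True)
        self.U2 = glorot(c.mlp_hidden, c.mlp_out)
        self.b2 = Tensor(np.zeros(c.mlp_out), requires_grad=True)

        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

    # ------------------------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {"E": self.E}
        for i, (Wa, ba, Wb, bb) in enumerate(self.res_params):
            params.update(
                {f"res{i}.Wa": Wa, f"res{i}.ba": ba, f"res{i}.Wb": Wb, f"res{i}.bb": bb}
            )
        if self.config.use_bilstm:
            for name, triple in (("fwd", self.lstm_fwd), ("bwd", self.lstm_bwd)):
                params[f"lstm_{name}.Wx"] = triple[0]
                params[f"lstm_{name}.Wh"] = triple[1]
                params[f"lstm_{name}.b"] = triple[2]
        else:
            params["W_proj"] = self.W_proj
        params.update(
            {
                "W1": self.W1,
                "W2": self.W2,
                "C": self.C,
                "W3": self.W3,
                "W4": self.W4,
                "U1": self.U1,
                "b1": self.b1,
                "U2": self.U2,
                "b2": self.b2,
            }
        )
        return params

    def init_code_matrix(
        self, descriptions: Sequence[CodeDescription], label_index: Mapping[str, int]
    ) -> None:
        """Initialize C rows from the mean embedding of description tokens.

        The e_dim-mean is tiled/trimmed to 2k; codes with empty descriptions
        keep their random rows.
        """
        two_k = 2 * self.config.k
        C = self.C.data
        for cd in descriptions:
            ids = cd.description_token_ids
            ids = ids[ids != PAD_ID]
            if len(ids) == 0 or cd.code not in label_index:
                continue
            mean = self.E.data[ids].mean(axis=0)
            reps = int(np.ceil(two_k / mean.shape[0]))
            C[label_index[cd.code]] = np.tile(mean, reps)[:two_k]

    # ------------------------------------------------------------------
    def forward(
        self,
        batch_ids: np.ndarray,
        mask: np.ndarray | None = None,
        train: bool = False,
    ) -> tuple[Tensor, Tensor, AttentionBundle]:
        """Run the network on a padded id batch.

        Returns pre-activation scores y_hat (B, L), probabilities y_tilde and
        the attention bundle.  ``mask`` marks real (non-PAD) positions; it is
        derived from PAD ids when omitted.
        """
        batch_ids = np.atleast_2d(np.asarray(batch_ids))
        if batch_ids.max(initial=0) >= self.config.vocab_size:
            raise ValueError("token id outside the model vocabulary")
        if mask is None:
            mask = batch_ids != PAD_ID
        mask = np.asarray(mask, dtype=bool)

        X = ag.embedding(self.E, batch_ids)  # (B, n, e)
        if train and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            dmask = self._dropout_rng.random(X.shape) < keep
            X = X * (dmask.astype(np.float64) / keep)
        for Wa, ba, Wb, bb in self.res_params:
            X = residual_block(X, Wa, ba, Wb, bb)
            X = X * mask[:, :, None].astype(np.float64)

        if self.config.use_bilstm:
            H = bilstm_encode(X, mask, self.lstm_fwd, self.lstm_bwd)
        else:
            H = (X @ self.W_proj) * mask[:, :, None].astype(np.float64)

        mode = self.config.ablation
        T_S = M_S = B_L = M_L = alpha = beta = None
        if mode in ("full", "self_only", "no_joint"):
            T_S, M_S = self_attention(H, mask, self.W1, self.W2)
        if mode in ("full", "label_only", "no_joint"):
            B_L, M_L = label_attention(
                H, mask, self.C, softmax=self.config.label_attention_softmax
            )

        if mode == "full":
            alpha, beta, V = joint_gate(M_S, M_L, self.W3, self.W4)
        elif mode == "self_only":
            V = M_S
        elif mode == "label_only":
            V = M_L
        else:  # no_joint: ungated sum, alpha = beta = 1 fixed
            V = M_S + M_L

        y_hat, y_tilde = predict_scores(V, self.U1, self.b1, self.U2, self.b2)
        bundle = AttentionBundle(
            T_S=None if T_S is None else T_S.data.copy(),
            B_L=None if B_L is None else B_L.data.copy(),
            M_S=None if M_S is None else M_S.data.copy(),
            M_L=None if M_L is None else M_L.data.copy(),
            alpha=None if alpha is None else alpha.data.copy(),
            beta=None if beta is None else beta.data.copy(),
            V=V.data.copy(),
        )
        return y_hat, y_tilde, bundle

    # ------------------------------------------------------------------
    def export_attention(
        self,
        doc: EncodedDocument,
        vocab: Vocabulary,
        code: str,
        label_index: Mapping[str, int],
    ) -> list[dict]:
        """Per-token attention weights for one document and one code.

        Emits one record per (non-PAD) position with the self-attention and
        label-attention weights; each weight column sums to 1.
        """
        if code not in label_index:
            raise KeyError(f"unknown code {code!r}")
        j = label_index[code]
        ids = doc.token_ids[None, :]
        _, _, bundle = self.forward(ids, train=False)
        rows = []
        for pos in range(doc.n):
            rows.append(
                {
                    "doc_id": doc.doc_id,
                    "code": code,
                    "position": pos,
                    "token": vocab.id_to_token.get(int(doc.token_ids[pos]), "<unk>"),
                    "self_attn": float(bundle.T_S[0, j, pos])
                    if bundle.T_S is not None
                    else float("nan"),
                    "label_attn": float(bundle.B_L[0, j, pos])
                    if bundle.B_L is not None
                    else float("nan"),
                }
            )
        return rows

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.parameters().items()}

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def config_dict(self) -> dict:
        return asdict(self.config)
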