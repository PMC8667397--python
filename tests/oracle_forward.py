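"""Straight-line NumPy re-computation of the full forward pass.

Independent of the package's autodiff graph: every stage is written out as
explicit loops/formulas directly from the model definition, reading only the
parameter arrays.  Used to cross-check ``JlanModel.forward``.
"""

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def straight_line_forward(model, ids):
    """Forward pass for a single unpadded document (1-D id array)."""
    c = model.config
    ids = np.asarray(ids)
    n = len(ids)
    k = c.k

    # embedding lookup
    X = model.E.data[ids]  # (n, e)

    # residual blocks: conv(k) -> relu -> conv(k), identity shortcut, relu
    for Wa, ba, Wb, bb in model.res_params:
        K = Wa.data.shape[0]
        left = (K - 1) // 2

        def conv(inp, W, b):
            out = np.zeros((n, W.shape[2]))
            for t in range(n):
                for tap in range(K):
                    src = t + tap - left
                    if 0 <= src < n:
                        out[t] += inp[src] @ W[tap]
                out[t] += b
            return out

        F = conv(np.maximum(conv(X, Wa.data, ba.data), 0.0), Wb.data, bb.data)
        X = np.maximum(F + X, 0.0)

    # Bi-LSTM, gate order i, f, g, o
    def lstm(X, Wx, Wh, b, reverse):
        h = np.zeros(k)
        cc = np.zeros(k)
        out = np.zeros((n, k))
        order = range(n - 1, -1, -1) if reverse else range(n)
        for t in order:
            z = X[t] @ Wx + h @ Wh + b
            i = sigmoid(z[:k])
            f = sigmoid(z[k : 2 * k])
            g = np.tanh(z[2 * k : 3 * k])
            o = sigmoid(z[3 * k :])
            cc = f * cc + i * g
            h = o * np.tanh(cc)
            out[t] = h
        return out

    hf = lstm(X, *[p.data for p in model.lstm_fwd], reverse=False)
    hb = lstm(X, *[p.data for p in model.lstm_bwd], reverse=True)
    H = np.concatenate([hf, hb], axis=1)  # (n, 2k)

    def row_softmax(scores):
        out = np.zeros_like(scores)
        for j in range(scores.shape[0]):
            e = np.exp(scores[j] - scores[j].max())
            out[j] = e / e.sum()
        return out

    # self-attention: T_S = softmax(W1 tanh(W2 H^T)) row-wise
    T_S = row_softmax(model.W1.data @ np.tanh(model.W2.data @ H.T))
    M_S = T_S @ H  # (L, 2k)

    # label attention: scores = C H^T
    raw = model.C.data @ H.T
    B_L = row_softmax(raw) if c.label_attention_softmax else raw
    M_L = B_L @ H

    # joint gate with the 0 < alpha + beta <= 1 constraint
    alpha = sigmoid(M_S @ model.W3.data)
    beta = sigmoid(M_L @ model.W4.data)
    s = alpha + beta
    scale = np.where(s > 1.0, 1.0 / s, 1.0)
    alpha, beta = alpha * scale, beta * scale
    V = np.concatenate([alpha[:, None] * M_S, beta[:, None] * M_L], axis=1)

    # shared two-layer MLP, sum-pooled
    Z = np.maximum(V @ model.U1.data + model.b1.data, 0.0) @ model.U2.data + model.b2.data
    y_hat = Z.sum(axis=1)
    return {
        "H": H, "T_S": T_S, "M_S": M_S, "B_L": B_L, "M_L": M_L,
        "alpha": alpha, "beta": beta, "V": V,
        "y_hat": y_hat, "y_tilde": sigmoid(y_hat),
    }
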