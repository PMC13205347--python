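"""Independent straight-line numpy oracles used to cross-check the model.

Everything here is written as direct dense linear algebra over explicit
adjacency matrices, deliberately sharing no code with the package's
edge-list / segment-reduction implementation paths.
"""

from __future__ import annotations

import numpy as np


def dense_adjacency(n: int, edges, self_loops: bool = True) -> np.ndarray:
    A = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        A[i, j] = True
    if self_loops:
        A |= np.eye(n, dtype=bool)
    return A


def dense_multihead_attention(X, Wq, Wk, Wv, heads, dk, A):
    """Neighborhood-masked softmax attention, head by head, dense."""
    outs = []
    for k in range(heads):
        sl = slice(k * dk, (k + 1) * dk)
        Q, K, V = X @ Wq[:, sl], X @ Wk[:, sl], X @ Wv[:, sl]
        S = Q @ K.T / np.sqrt(dk)
        S = np.where(A, S, -np.inf)
        S = S - S.max(axis=1, keepdims=True)
        W = np.exp(S)
        W /= W.sum(axis=1, keepdims=True)
        outs.append(W @ V)
    return np.concatenate(outs, axis=1)


def dense_gcn(H, W, b, A):
    """Symmetric-normalized graph convolution (self-loops in A), linear part."""
    deg = A.sum(axis=1).astype(float)
    Dinv = np.diag(1.0 / np.sqrt(deg))
    Ahat = Dinv @ A.astype(float) @ Dinv
    return Ahat @ H @ W + b


def dense_sage(H, W, b, A):
    """Mean-aggregating SAGE layer with self/neighbor concat + ReLU."""
    mean = A.astype(float) / A.sum(axis=1, keepdims=True)
    out = np.concatenate([H, mean @ H], axis=1) @ W + b
    return np.maximum(out, 0.0)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def cbam_reference(F, w1, b1, w2, b2, conv_w, conv_b):
    """Channel then spatial attention on a single (C,H,W) map."""
    C, H, W = F.shape
    gap = F.mean(axis=(1, 2))
    gmp = F.max(axis=(1, 2))
    mlp = lambda g: np.maximum(g @ w1 + b1, 0.0) @ w2 + b2
    mc = sigmoid(mlp(gap) + mlp(gmp))
    refined = F * mc[:, None, None]
    avg_c = refined.mean(axis=0)
    max_c = refined.max(axis=0)
    stacked = np.stack([avg_c, max_c])          # (2, H, W)
    k = conv_w.shape[-1]
    pad = k // 2
    padded = np.pad(stacked, ((0, 0), (pad, pad), (pad, pad)))
    conv = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            conv[i, j] = np.sum(padded[:, i:i + k, j:j + k] * conv_w[0]) + conv_b[0]
    ms = sigmoid(conv)
    return refined * ms[None], mc, ms


def joint_gate_reference(map_h, map_c, w1, b1, w2, b2):
    """Cross-branch gate on single (C,H,W) maps."""
    g_h = map_h.mean(axis=(1, 2))
    g_c = map_c.mean(axis=(1, 2))
    gate = sigmoid(np.maximum(np.concatenate([g_h, g_c]) @ w1 + b1, 0.0) @ w2 + b2)
    c = map_h.shape[0]
    return map_h * gate[:c, None, None], map_c * gate[c:, None, None], gate


def residual_fusion_reference(u, w1, b1, gamma, beta, rm, rv, eps,
                              w2, b2, wskip, bskip):
    """Eval-mode residual fusion on a batch of joint vectors."""
    h = np.maximum(u @ w1 + b1, 0.0)
    h = (h - rm) / np.sqrt(rv + eps) * gamma + beta
    return h @ w2 + b2 + u @ wskip + bskip


def auc_bruteforce(labels, scores):
    """Exhaustive pairwise concordance count (ties count 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def tanimoto_bruteforce(fp_a, fp_b):
    """Set-based Tanimoto over fingerprint on-bit index sets."""
    a = {i for i, v in enumerate(fp_a) if v}
    b = {i for i, v in enumerate(fp_b) if v}
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
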