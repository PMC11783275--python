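"""Naive loop implementations of every network stage.

These are deliberately slow, scalar-level re-derivations of the
architecture used as independent oracles: each vectorized stage must
reproduce them within tight tolerance on small random instances.
"""

from __future__ import annotations

import numpy as np


def naive_conv(D, params, cfg):
    """Sliding-window triple loop, zero padding, ReLU."""
    L, d = D.shape
    m, w = cfg.m, cfg.w
    left = (w - 1) // 2
    C = np.zeros((L, m))
    for j in range(L):
        for f in range(m):
            acc = params.bc[f]
            for t in range(w):
                src = j - left + t
                if 0 <= src < L:
                    for c in range(d):
                        acc += D[src, c] * params.Wc[t, c, f]
            C[j, f] = max(acc, 0.0)
    return C


def naive_attention(C, params, cfg):
    """Per-position scalar-loop multi-head attention with residual."""
    L, m = C.shape
    h, r = cfg.h, cfg.r
    scale = 1.0 / np.sqrt(r) if cfg.sqrt_scale else 1.0 / r
    blocks = []
    for i in range(h):
        Q = C @ params.AQ[i]
        K = C @ params.AK[i]
        V = C @ params.AV[i]
        Zi = np.zeros((L, r))
        for q in range(L):
            scores = np.array([float(Q[q] @ K[kk]) * scale for kk in range(L)])
            weights = np.exp(scores - scores.max())
            weights = weights / weights.sum()
            for kk in range(L):
                Zi[q] += weights[kk] * V[kk]
        blocks.append(Zi)
    return np.concatenate(blocks, axis=1) @ params.AO + C


def naive_ffn(Z, params):
    """Row-by-row feed-forward with residual."""
    F = np.zeros_like(Z)
    for j in range(Z.shape[0]):
        hidden = np.maximum(Z[j] @ params.W1 + params.b1, 0.0)
        F[j] = hidden @ params.W2 + params.b2 + Z[j]
    return F


def naive_pool(F):
    """Column means and maxima via explicit loops."""
    L, m = F.shape
    pave = np.array([sum(F[j, c] for j in range(L)) / L for c in range(m)])
    pmax = np.array([max(F[j, c] for j in range(L)) for c in range(m)])
    return np.concatenate([pave, pmax])


def naive_output(P, params):
    """Scalar-loop dot product plus bias."""
    return float(sum(p * wo for p, wo in zip(P, params.wO)) + params.bO)


def naive_forward(D, params, cfg):
    """Composition of all naive stages."""
    C = naive_conv(D, params, cfg)
    Z = naive_attention(C, params, cfg)
    F = naive_ffn(Z, params)
    return naive_output(naive_pool(F), params)
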