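"""The ddG regression head: 1D conv, one transformer-encoder layer, pooling.

Architecture, applied to the L x d difference encoding D of a variation:

1. A 1D convolution with m filters of width w (zero same-padding, ReLU)
   projects D to C (L x m), extracting local context.
2. One transformer-encoder layer: h-head scaled dot-product self-attention

       Q_i = C A^Q_i,  K_i = C A^K_i,  V_i = C A^V_i
       Z_i = softmax(Q_i K_i^T / sqrt(r)) V_i,        r = m / h
       Z   = [Z_1 .. Z_h] A^O + C                      (residual)

   followed by a position-wise feed-forward network with residual:

       f_j = ReLU(z_j W1 + b1) W2 + b2 + z_j

   There is no positional encoding, layer normalization, or dropout: the
   encoder is purely the equations above (optional layer norm is available
   behind a non-default flag), so the post-conv pipeline is permutation-
   invariant in the rows of C.
3. Global average and max pooling over positions collapse F (L x m) to a
   2m-vector P = [p_ave, p_max], and a linear head yields the scalar
   prediction y = P . wO + bO, in kcal/mol (negative = destabilizing).

Batched inference zero-pads variable-length inputs and masks padded
positions out of both the attention softmax (additive -inf) and the
pooling, so batched results equal single-sequence results.

All arithmetic is float64 NumPy. :func:`backward_batch` implements the
exact reverse-mode gradients of the forward pass; training lives in
:mod:`embddg.train`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ModelConfig",
    "ModelParams",
    "ActivationState",
    "PRESETS",
    "conv1d_forward",
    "multi_head_attention",
    "attention_weights",
    "position_ffn",
    "pool_concat",
    "output_head",
    "forward",
    "forward_state",
    "forward_batch",
    "backward_batch",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the prediction head.

    m: conv filter count (also the encoder width); w: conv filter width;
    h: attention heads; s: FFN hidden size; r = m/h is the per-head
    dimension. ``sqrt_scale`` selects the conventional 1/sqrt(r) attention
    scaling (default); plain 1/r is available for sensitivity checks.
    ``layer_norm`` is off by default (the encoder equations carry residual
    connections only).
    """

    m: int = 128
    w: int = 15
    h: int = 8
    s: int = 512
    sqrt_scale: bool = True
    layer_norm: bool = False

    def __post_init__(self) -> None:
        if self.m < 1 or self.w < 1 or self.h < 1 or self.s < 1:
            raise ValueError("all of m, w, h, s must be positive")
        if self.m % self.h != 0:
            raise ValueError(f"m={self.m} not divisible by h={self.h}")

    @property
    def r(self) -> int:
        """Per-head attention dimension m/h."""
        return self.m // self.h

    def to_dict(self) -> dict:
        return {
            "m": self.m, "w": self.w, "h": self.h, "s": self.s,
            "sqrt_scale": self.sqrt_scale, "layer_norm": self.layer_norm,
        }


#: The hyperparameter grid explored in cross-validation; model4 (m=128,
#: h=8, s=512, hence r=16) is the production configuration.
PRESETS: dict[str, ModelConfig] = {
    "model0": ModelConfig(m=32, h=2, s=128),
    "model1": ModelConfig(m=64, h=2, s=256),
    "model2": ModelConfig(m=64, h=4, s=256),
    "model3": ModelConfig(m=128, h=4, s=512),
    "model4": ModelConfig(m=128, h=8, s=512),
    "model5": ModelConfig(m=256, h=8, s=1024),
}


@dataclass
class ModelParams:
    """All learnable weights; shapes are fixed by (config, input dim d)."""

    Wc: np.ndarray   # (w, d, m) conv filters
    bc: np.ndarray   # (m,)
    AQ: np.ndarray   # (h, m, r)
    AK: np.ndarray   # (h, m, r)
    AV: np.ndarray   # (h, m, r)
    AO: np.ndarray   # (m, m)
    W1: np.ndarray   # (m, s)
    b1: np.ndarray   # (s,)
    W2: np.ndarray   # (s, m)
    b2: np.ndarray   # (m,)
    wO: np.ndarray   # (2m,)
    bO: np.ndarray   # scalar ()

    @property
    def d(self) -> int:
        return self.Wc.shape[1]

    @classmethod
    def init(cls, cfg: ModelConfig, d: int, rng: np.random.Generator,
             scale: float = 1.0) -> "ModelParams":
        """He initialization for ReLU layers, Glorot for the projections.

        ``scale`` multiplies all weight-matrix magnitudes; values < 1 start
        the optimizer closer to the low-norm regime.
        """
        m, w, h, r, s = cfg.m, cfg.w, cfg.h, cfg.r, cfg.s
        he = lambda shape, fan: rng.standard_normal(shape) * (scale * np.sqrt(2.0 / fan))
        glorot = lambda shape, fi, fo: rng.standard_normal(shape) * (
            scale * np.sqrt(2.0 / (fi + fo)))
        return cls(
            Wc=he((w, d, m), w * d),
            bc=np.zeros(m),
            AQ=glorot((h, m, r), m, r),
            AK=glorot((h, m, r), m, r),
            AV=glorot((h, m, r), m, r),
            AO=glorot((m, m), m, m),
            W1=he((m, s), m),
            b1=np.zeros(s),
            W2=glorot((s, m), s, m),
            b2=np.zeros(m),
            wO=glorot((2 * m,), 2 * m, 1),
            bO=np.zeros(()),
        )

    def as_dict(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def copy(self) -> "ModelParams":
        return ModelParams(**{k: v.copy() for k, v in self.as_dict().items()})

    def check_shapes(self, cfg: ModelConfig) -> None:
        m, w, h, r, s = cfg.m, cfg.w, cfg.h, cfg.r, cfg.s
        expected = {
            "Wc": (w, self.d, m), "bc": (m,),
            "AQ": (h, m, r), "AK": (h, m, r), "AV": (h, m, r), "AO": (m, m),
            "W1": (m, s), "b1": (s,), "W2": (s, m), "b2": (m,),
            "wO": (2 * m,), "bO": (),
        }
        for name, shape in expected.items():
            got = getattr(self, name).shape
            if got != shape:
                raise ValueError(f"parameter {name} has shape {got}, expected {shape}")
        for name, arr in self.as_dict().items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"parameter {name} contains non-finite values")


@dataclass
class ActivationState:
    """Intermediate activations of one forward pass (single instance)."""

    C: np.ndarray            # (L, m)
    attn: np.ndarray         # (h, L, L) softmax weights per head
    Z: np.ndarray            # (L, m)
    F: np.ndarray            # (L, m)
    pave: np.ndarray         # (m,)
    pmax: np.ndarray         # (m,)
    P: np.ndarray            # (2m,)
    y_hat: float


# ---------------------------------------------------------------------------
# batched forward / backward (the workhorse)
# ---------------------------------------------------------------------------

def _check_input(D: np.ndarray, params: ModelParams) -> None:
    if D.ndim != 3:
        raise ValueError(f"expected (B, L, d) input, got shape {D.shape}")
    if D.shape[2] != params.d:
        raise ValueError(
            f"channel mismatch: input d={D.shape[2]}, filters expect d={params.d}"
        )


def _softmax_lastaxis(S: np.ndarray) -> np.ndarray:
    # max-subtraction keeps exp() in range for any finite scores
    shifted = S - S.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _layer_norm(X: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, keepdims=True)
    return (X - mu) / (sd + eps)


def im2col(D: np.ndarray, w: int) -> np.ndarray:
    """Unfold (B, L, d) into conv windows (B, L, w*d), zero same-padding.

    Precomputing this once per dataset and passing it to
    :func:`forward_batch` via ``win`` avoids rebuilding windows every
    minibatch during training.
    """
    B, L, d = D.shape
    left, right = (w - 1) // 2, w // 2
    Dp = np.pad(D, ((0, 0), (left, right), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(Dp, w, axis=1)  # (B,L,d,w)
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, L, w * d)


def forward_batch(
    D: np.ndarray,
    mask: Optional[np.ndarray],
    params: ModelParams,
    cfg: ModelConfig,
    return_cache: bool = False,
    win: Optional[np.ndarray] = None,
):
    """Forward pass on a (B, L, d) batch; ``mask`` is (B, L) bool, True = valid.

    Returns the (B,) prediction vector, plus the activation cache needed by
    :func:`backward_batch` when ``return_cache`` is set. Padded positions
    (mask False) receive zero attention weight and are excluded from
    pooling, so padding never changes a sequence's prediction.

    ``win`` optionally supplies precomputed :func:`im2col` windows for the
    same input; the caller then guarantees that padded rows of D were zero
    when the windows were built.
    """
    D = np.asarray(D, dtype=np.float64)
    _check_input(D, params)
    B, L, d = D.shape
    if mask is None:
        mask = np.ones((B, L), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (B, L):
            raise ValueError(f"mask shape {mask.shape} != {(B, L)}")
        if not mask.any(axis=1).all():
            raise ValueError("every instance needs at least one unmasked position")
        if not mask.all() and win is None:
            D = D * mask[:, :, None]  # padded rows must read as zero padding
    m, w, h, r = cfg.m, cfg.w, cfg.h, cfg.r

    # --- conv with zero same-padding (output keeps L rows) ---
    if win is None:
        win = im2col(D, w)
    Wc_flat = params.Wc.reshape(w * d, m)
    Cpre = win @ Wc_flat + params.bc
    C = np.maximum(Cpre, 0.0)

    # --- multi-head self-attention with residual ---
    scale = 1.0 / np.sqrt(r) if cfg.sqrt_scale else 1.0 / r
    key_valid = mask[:, None, :]  # (B, 1, L); False keys get zero weight
    Q = np.empty((h, B, L, r))
    K = np.empty((h, B, L, r))
    V = np.empty((h, B, L, r))
    A = np.empty((h, B, L, L))
    Zc = np.empty((B, L, m))
    for i in range(h):
        Q[i] = C @ params.AQ[i]
        K[i] = C @ params.AK[i]
        V[i] = C @ params.AV[i]
        S = Q[i] @ K[i].swapaxes(1, 2) * scale
        # masked softmax without non-finite intermediates: max-subtract over
        # valid keys, exponentiate only there, renormalize. Shifted scores
        # are clamped at -700 (exp underflow edge): weights that small are
        # exactly 0 after division, and the clamp keeps libm off the slow
        # subnormal path.
        smax = S.max(axis=-1, keepdims=True, where=key_valid, initial=-np.inf)
        e = np.zeros_like(S)
        np.exp(np.maximum(S - smax, -700.0), out=e, where=key_valid)
        A[i] = e / e.sum(axis=-1, keepdims=True)
        Zc[:, :, i * r : (i + 1) * r] = A[i] @ V[i]
    Z = Zc @ params.AO + C
    if cfg.layer_norm:
        Z = _layer_norm(Z)

    # --- position-wise FFN with residual ---
    H1 = Z @ params.W1 + params.b1
    Hr = np.maximum(H1, 0.0)
    F = Hr @ params.W2 + params.b2 + Z
    if cfg.layer_norm:
        F = _layer_norm(F)

    # --- pooling over valid positions, then linear head ---
    maskf = mask[:, :, None].astype(np.float64)
    n_valid = maskf.sum(axis=1)                       # (B, 1)
    pave = (F * maskf).sum(axis=1) / n_valid          # (B, m)
    F_neg = np.where(mask[:, :, None], F, -np.inf)
    argmax = F_neg.argmax(axis=1)                     # (B, m)
    pmax = np.take_along_axis(F, argmax[:, None, :], axis=1)[:, 0, :]
    P = np.concatenate([pave, pmax], axis=1)          # (B, 2m)
    y_hat = P @ params.wO + float(params.bO)

    if not return_cache:
        return y_hat
    cache = {
        "cfg": cfg, "mask": mask, "maskf": maskf, "n_valid": n_valid,
        "win": win, "Cpre": Cpre, "C": C, "Q": Q, "K": K, "V": V, "A": A,
        "Zc": Zc, "Z": Z, "H1": H1, "Hr": Hr, "F": F,
        "argmax": argmax, "P": P, "scale": scale,
    }
    return y_hat, cache


def backward_batch(
    dy: np.ndarray, cache: dict, params: ModelParams
) -> dict[str, np.ndarray]:
    """Gradients of sum_b dy_b * y_hat_b w.r.t. every parameter.

    ``dy`` is the (B,) upstream gradient (for MSE, 2 (y_hat - y) / N).
    Only parameter gradients are returned; the input D is not trainable.
    Not defined for ``layer_norm`` configurations.
    """
    cfg: ModelConfig = cache["cfg"]
    if cfg.layer_norm:
        raise NotImplementedError("gradients are implemented for the plain encoder")
    m, w, h, r = cfg.m, cfg.w, cfg.h, cfg.r
    C, Zc, Z, Hr, F = cache["C"], cache["Zc"], cache["Z"], cache["Hr"], cache["F"]
    B, L, _ = C.shape
    dy = np.asarray(dy, dtype=np.float64)

    # linear head
    dP = dy[:, None] * params.wO[None, :]
    g_wO = cache["P"].T @ dy
    g_bO = np.asarray(dy.sum())

    # pooling: average spreads over valid rows, max routes to the argmax row
    dpave, dpmax = dP[:, :m], dP[:, m:]
    dF = cache["maskf"] * dpave[:, None, :] / cache["n_valid"][:, None, :]
    dFmax = np.zeros_like(F)
    np.put_along_axis(dFmax, cache["argmax"][:, None, :], dpmax[:, None, :], axis=1)
    dF = dF + dFmax

    # FFN (+ residual)
    dZ = dF.copy()
    dHr = dF @ params.W2.T
    g_W2 = Hr.reshape(-1, cfg.s).T @ dF.reshape(-1, m)
    g_b2 = dF.sum(axis=(0, 1))
    dH1 = dHr * (cache["H1"] > 0)
    dZ += dH1 @ params.W1.T
    g_W1 = Z.reshape(-1, m).T @ dH1.reshape(-1, cfg.s)
    g_b1 = dH1.sum(axis=(0, 1))

    # attention (+ residual)
    dC = dZ.copy()
    dZc = dZ @ params.AO.T
    g_AO = Zc.reshape(-1, m).T @ dZ.reshape(-1, m)
    g_AQ = np.empty_like(params.AQ)
    g_AK = np.empty_like(params.AK)
    g_AV = np.empty_like(params.AV)
    Cflat = C.reshape(-1, m)
    scale = cache["scale"]
    for i in range(h):
        Ai = cache["A"][i]
        dZi = dZc[:, :, i * r : (i + 1) * r]
        dA = dZi @ cache["V"][i].swapaxes(1, 2)
        dVi = Ai.swapaxes(1, 2) @ dZi
        dS = Ai * (dA - (dA * Ai).sum(axis=-1, keepdims=True))
        dQi = dS @ cache["K"][i] * scale
        dKi = dS.swapaxes(1, 2) @ cache["Q"][i] * scale
        g_AQ[i] = Cflat.T @ dQi.reshape(-1, r)
        g_AK[i] = Cflat.T @ dKi.reshape(-1, r)
        g_AV[i] = Cflat.T @ dVi.reshape(-1, r)
        dC += dQi @ params.AQ[i].T + dKi @ params.AK[i].T + dVi @ params.AV[i].T

    # conv
    dCpre = dC * (cache["Cpre"] > 0)
    g_Wc = (cache["win"].reshape(-1, w * params.d).T
            @ dCpre.reshape(-1, m)).reshape(w, params.d, m)
    g_bc = dCpre.sum(axis=(0, 1))

    return {
        "Wc": g_Wc, "bc": g_bc, "AQ": g_AQ, "AK": g_AK, "AV": g_AV,
        "AO": g_AO, "W1": g_W1, "b1": g_b1, "W2": g_W2, "b2": g_b2,
        "wO": g_wO, "bO": g_bO,
    }


# ---------------------------------------------------------------------------
# single-instance stage API
# ---------------------------------------------------------------------------

def conv1d_forward(D: np.ndarray, params: ModelParams, cfg: ModelConfig) -> np.ndarray:
    """ReLU 1D convolution of the L x d difference matrix; output is L x m."""
    D = np.atleast_2d(np.asarray(D, dtype=np.float64))
    B, L, d = 1, *D.shape
    _check_input(D[None], params)
    w, m = cfg.w, cfg.m
    left, right = (w - 1) // 2, w // 2
    Dp = np.pad(D, ((left, right), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(Dp, w, axis=0)  # (L, d, w)
    win = np.ascontiguousarray(win.transpose(0, 2, 1)).reshape(L, w * d)
    return np.maximum(win @ params.Wc.reshape(w * d, m) + params.bc, 0.0)


def attention_weights(
    C: np.ndarray, params: ModelParams, cfg: ModelConfig,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-head softmax attention matrices, shape (h, L, L); rows sum to 1."""
    C = np.asarray(C, dtype=np.float64)
    L = C.shape[0]
    scale = 1.0 / np.sqrt(cfg.r) if cfg.sqrt_scale else 1.0 / cfg.r
    gate = 0.0 if mask is None else np.where(np.asarray(mask, bool)[None, :], 0.0, -np.inf)
    out = np.empty((cfg.h, L, L))
    for i in range(cfg.h):
        S = (C @ params.AQ[i]) @ (C @ params.AK[i]).T * scale + gate
        out[i] = _softmax_lastaxis(S)
    return out


def multi_head_attention(
    C: np.ndarray, params: ModelParams, cfg: ModelConfig,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Multi-head self-attention with output projection and residual, L x m."""
    C = np.asarray(C, dtype=np.float64)
    if C.shape[1] != cfg.m:
        raise ValueError(f"C has {C.shape[1]} columns, expected m={cfg.m}")
    A = attention_weights(C, params, cfg, mask)
    Zc = np.concatenate(
        [A[i] @ (C @ params.AV[i]) for i in range(cfg.h)], axis=1
    )
    Z = Zc @ params.AO + C
    return _layer_norm(Z) if cfg.layer_norm else Z


def position_ffn(Z: np.ndarray, params: ModelParams, cfg: ModelConfig) -> np.ndarray:
    """Row-wise f_j = ReLU(z_j W1 + b1) W2 + b2 + z_j."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[1] != cfg.m:
        raise ValueError(f"Z has {Z.shape[1]} columns, expected m={cfg.m}")
    F = np.maximum(Z @ params.W1 + params.b1, 0.0) @ params.W2 + params.b2 + Z
    return _layer_norm(F) if cfg.layer_norm else F


def pool_concat(F: np.ndarray, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Concatenated global average and max pooling over (unmasked) rows."""
    F = np.asarray(F, dtype=np.float64)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("all positions masked: pooling undefined")
        F = F[mask]
    if F.shape[0] < 1:
        raise ValueError("pooling requires at least one position")
    return np.concatenate([F.mean(axis=0), F.max(axis=0)])


def output_head(P: np.ndarray, params: ModelParams) -> float:
    """Linear read-out y = P . wO + bO."""
    P = np.asarray(P, dtype=np.float64)
    if P.shape != params.wO.shape:
        raise ValueError(f"P has shape {P.shape}, expected {params.wO.shape}")
    return float(P @ params.wO + params.bO)


def forward_state(D: np.ndarray, params: ModelParams, cfg: ModelConfig) -> ActivationState:
    """Full single-instance forward pass retaining intermediates."""
    C = conv1d_forward(D, params, cfg)
    attn = attention_weights(C, params, cfg)
    Z = multi_head_attention(C, params, cfg)
    F = position_ffn(Z, params, cfg)
    P = pool_concat(F)
    m = cfg.m
    return ActivationState(
        C=C, attn=attn, Z=Z, F=F,
        pave=P[:m], pmax=P[m:], P=P, y_hat=output_head(P, params),
    )


def forward(D: np.ndarray, params: ModelParams, cfg: ModelConfig) -> float:
    """Predicted ddG (kcal/mol) for one difference-encoded variation."""
    return forward_state(D, params, cfg).y_hat


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(path: str | Path, params: ModelParams, cfg: ModelConfig,
                    meta: Optional[dict] = None) -> None:
    """Write config + weights to an ``.npz`` container with a JSON header."""
    header = {
        "format_version": _CHECKPOINT_VERSION,
        "config": cfg.to_dict(),
        "d": params.d,
        "meta": meta or {},
    }
    arrays = {f"param_{k}": v for k, v in params.as_dict().items()}
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelParams, ModelConfig, dict]:
    """Read a checkpoint; returns (params, config, metadata)."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("format_version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version in {path}")
        params = ModelParams(**{
            k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")
        })
    cfg = ModelConfig(**header["config"])
    params.check_shapes(cfg)
    return params, cfg, header.get("meta", {})
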