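"""Multi-head scaled dot-product cross- and self-attention.

Queries come from one sequence and keys/values from the other: the
protein context C^P is built from protein queries attending drug
keys/values, and the drug context C^D from drug queries attending
protein keys/values. Per head i,

    Q_i = Y W_i^Q,  K_i = Y' W_i^K,  V_i = Y' W_i^V
    AttentionWeight_i = softmax(Q_i K_i^T / sqrt(d))
    head_i = AttentionWeight_i . V_i
    Multihead = concat(head_1..head_h) W_0
    C = concat(Q_1..Q_h) + Multihead

where d is the per-head column dimension (h.d equals the hidden size;
default h=4, d=96, hidden 384). The residual adds the feature-axis
concatenation of the per-head queries so that widths match the
multi-head output. Key-side PAD positions are excluded from the softmax
by an additive mask (switchable off for a mask-free fidelity mode), and
PAD query rows are zeroed in the context.

The softmax denominator uses sqrt(d) (standard scaled dot-product); a
plain-d variant is available via ``scale_mode="d"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import (Parameter, Tensor, add, concat, masked_softmax,
                        matmul, mul, reshape, transpose)
from .encoding import EmbeddingMatrix


@dataclass
class ProjectionParams:
    """Per-head Q/K/V projection weights plus the output projection W_0."""

    Wq: Parameter  # (h, in_dim, d)
    Wk: Parameter
    Wv: Parameter
    W0: Parameter  # (h*d, h*d)
    h: int
    d: int

    @property
    def parameters(self) -> list[Parameter]:
        return [self.Wq, self.Wk, self.Wv, self.W0]


def init_projection(in_dim_q: int, in_dim_kv: int | None = None,
                    h: int = 4, d: int = 96,
                    rng: np.random.Generator | None = None
                    ) -> ProjectionParams:
    """Uniform init scaled by input dimension, U(-1/sqrt(fan_in), +).

    Query projections read the query-side embedding (width in_dim_q);
    key/value projections read the other sequence (width in_dim_kv,
    defaulting to in_dim_q).
    """
    rng = rng or np.random.default_rng()
    if in_dim_kv is None:
        in_dim_kv = in_dim_q

    def u(shape, fan_in):
        lim = 1.0 / np.sqrt(fan_in)
        return Parameter(rng.uniform(-lim, lim, size=shape))

    return ProjectionParams(
        Wq=u((h, in_dim_q, d), in_dim_q), Wk=u((h, in_dim_kv, d), in_dim_kv),
        Wv=u((h, in_dim_kv, d), in_dim_kv), W0=u((h * d, h * d), h * d),
        h=h, d=d)


@dataclass
class AttentionBundle:
    """Attention weights, per-head outputs, and the context matrix."""

    weights: np.ndarray  # (h, Lq, Lk) row-stochastic over unmasked keys
    heads: np.ndarray    # (h, Lq, d)
    context: Tensor      # (Lq, h*d)
    query_mask: np.ndarray


# -- spec-level single-matrix operations --------------------------------

def project(emb: EmbeddingMatrix, params: ProjectionParams,
            role: str) -> Tensor:
    """Per-head linear projection: output_i = embedding . W_i^role."""
    W = {"Q": params.Wq, "K": params.Wk, "V": params.Wv}[role]
    if emb.values.shape[-1] != W.shape[1]:
        raise ValueError("embedding feature dim does not match projection")
    return matmul(reshape(emb.values, (1,) + tuple(emb.values.shape)), W)


def attention_weights(Qi: np.ndarray, Ki: np.ndarray, d: int,
                      key_mask: np.ndarray | None = None,
                      scale_mode: str = "sqrt") -> np.ndarray:
    """Row-wise masked softmax of Q K^T / sqrt(d) for a single head."""
    scale = np.sqrt(d) if scale_mode == "sqrt" else float(d)
    scores = Tensor(np.asarray(Qi) @ np.asarray(Ki).T / scale)
    return masked_softmax(scores, key_mask).data


def attend(weights: np.ndarray, Vi: np.ndarray) -> np.ndarray:
    """head = weights . V_i."""
    weights, Vi = np.asarray(weights), np.asarray(Vi)
    if weights.shape[-1] != Vi.shape[0]:
        raise ValueError("weights columns must equal value rows")
    return weights @ Vi


# -- batched multi-head core --------------------------------------------

def multihead_context(q_x: Tensor, kv_x: Tensor, params: ProjectionParams,
                      key_mask: np.ndarray | None,
                      query_mask: np.ndarray | None,
                      scale_mode: str = "sqrt"
                      ) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Batched context computation.

    q_x: (B, Lq, Din), kv_x: (B, Lk, Din); key_mask/query_mask: (B, L)
    boolean or None to disable masking. Returns (context (B, Lq, h*d),
    attention weights (B, h, Lq, Lk), heads (B, h, Lq, d)).
    """
    B, Lq, _ = q_x.shape
    Lk = kv_x.shape[1]
    h, d = params.h, params.d

    q4 = reshape(q_x, (B, 1, Lq, q_x.shape[2]))
    kv4 = reshape(kv_x, (B, 1, Lk, kv_x.shape[2]))
    Q = matmul(q4, params.Wq)   # (B, h, Lq, d)
    K = matmul(kv4, params.Wk)  # (B, h, Lk, d)
    V = matmul(kv4, params.Wv)

    scale = 1.0 / (np.sqrt(d) if scale_mode == "sqrt" else float(d))
    scores = mul(matmul(Q, transpose(K, (0, 1, 3, 2))), np.float32(scale))
    km = None if key_mask is None else key_mask[:, None, None, :]
    W = masked_softmax(scores, km)          # (B, h, Lq, Lk)
    heads = matmul(W, V)                    # (B, h, Lq, d)

    def concat_heads(x):  # (B, h, Lq, d) -> (B, Lq, h*d)
        return reshape(transpose(x, (0, 2, 1, 3)), (B, Lq, h * d))

    mh = matmul(concat_heads(heads), params.W0)
    context = add(concat_heads(Q), mh)
    if query_mask is not None:
        context = mul(context, query_mask[:, :, None].astype(np.float32))
    return context, W.data, heads.data


def _single(emb: EmbeddingMatrix, masked: bool):
    x = reshape(emb.values, (1,) + tuple(emb.values.shape))
    mask = emb.mask[None, :] if masked else None
    return x, mask


def cross_context(query_emb: EmbeddingMatrix, kv_emb: EmbeddingMatrix,
                  params: ProjectionParams, masked: bool = True,
                  scale_mode: str = "sqrt") -> AttentionBundle:
    """Context of the query sequence conditioned on the other sequence."""
    qx, qm = _single(query_emb, masked)
    kx, km = _single(kv_emb, masked)
    ctx, W, heads = multihead_context(qx, kx, params, km, qm, scale_mode)
    return AttentionBundle(weights=W[0], heads=heads[0],
                           context=reshape(ctx, tuple(ctx.shape[1:])),
                           query_mask=query_emb.mask)


def self_context(emb: EmbeddingMatrix, params: ProjectionParams,
                 masked: bool = True,
                 scale_mode: str = "sqrt") -> AttentionBundle:
    """Self-attention: query, key and value all from one embedding."""
    return cross_context(emb, emb, params, masked=masked,
                         scale_mode=scale_mode)
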