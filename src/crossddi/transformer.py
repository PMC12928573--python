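"""Transformer building blocks shared by the graph and sequence encoders.

Both views encode a set/sequence of d-dimensional tokens with the same
per-layer computation: per head i,

    Q_i = X W_Q^(i),  K_i = X W_K^(i),  V_i = X W_V^(i)
    Attention_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i            (row-wise)
    MultiHead(X) = Concat(Attention_1, ..., Attention_h) W^O

followed by a position-wise feed-forward sublayer, each wrapped in a residual
connection with post-layer normalization.  The h per-head projections are
stored as single d x d matrices and sliced by reshaping (h * d_k = d).

Padding is handled with a boolean mask (True = real token): padded keys
receive a large negative score bias before the softmax, and callers exclude
padded rows when pooling.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

_MASK_BIAS = -1e30


def xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


def init_attention(rng: np.random.Generator, d: int, prefix: str) -> dict[str, Tensor]:
    return {
        f"{prefix}.Wq": Tensor(xavier(rng, d, d), requires_grad=True),
        f"{prefix}.Wk": Tensor(xavier(rng, d, d), requires_grad=True),
        f"{prefix}.Wv": Tensor(xavier(rng, d, d), requires_grad=True),
        f"{prefix}.Wo": Tensor(xavier(rng, d, d), requires_grad=True),
    }


def init_layer(rng: np.random.Generator, d: int, d_ff: int, prefix: str) -> dict[str, Tensor]:
    params = init_attention(rng, d, f"{prefix}.attn")
    params.update(
        {
            f"{prefix}.ffn.W1": Tensor(xavier(rng, d, d_ff), requires_grad=True),
            f"{prefix}.ffn.b1": Tensor(np.zeros(d_ff), requires_grad=True),
            f"{prefix}.ffn.W2": Tensor(xavier(rng, d_ff, d), requires_grad=True),
            f"{prefix}.ffn.b2": Tensor(np.zeros(d), requires_grad=True),
            f"{prefix}.ln1.g": Tensor(np.ones(d), requires_grad=True),
            f"{prefix}.ln1.b": Tensor(np.zeros(d), requires_grad=True),
            f"{prefix}.ln2.g": Tensor(np.ones(d), requires_grad=True),
            f"{prefix}.ln2.b": Tensor(np.zeros(d), requires_grad=True),
        }
    )
    return params


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    return centred / (var + eps).sqrt() * gain + bias


def multi_head_self_attention(
    x: Tensor,
    params: dict[str, Tensor],
    prefix: str,
    heads: int,
    mask: np.ndarray | None = None,
) -> Tensor:
    """Multi-head scaled dot-product self-attention on ``x`` of shape (B, T, d).

    No positional information is injected here: the tokens form a set, and the
    output rows permute exactly as the input rows do.  ``mask`` is (B, T) with
    True marking real tokens; masked keys are excluded from every softmax row.
    """
    b, t, d = x.shape
    if d % heads != 0:
        raise ValueError(f"head count {heads} must divide width {d}")
    d_k = d // heads

    def split(y: Tensor) -> Tensor:  # (B, T, d) -> (B, h, T, d_k)
        return y.reshape(b, t, heads, d_k).transpose(0, 2, 1, 3)

    q = split(x @ params[f"{prefix}.Wq"])
    k = split(x @ params[f"{prefix}.Wk"])
    v = split(x @ params[f"{prefix}.Wv"])
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    if mask is not None:
        bias = np.where(mask[:, None, None, :], 0.0, _MASK_BIAS)
        scores = scores + Tensor(bias)
    attn = scores.softmax()
    out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
    return out @ params[f"{prefix}.Wo"]


def transformer_layer(
    x: Tensor,
    params: dict[str, Tensor],
    prefix: str,
    heads: int,
    mask: np.ndarray | None = None,
) -> Tensor:
    """One post-norm encoder layer: MHSA and FFN sublayers with residuals."""
    attended = multi_head_self_attention(x, params, f"{prefix}.attn", heads, mask)
    x = layer_norm(x + attended, params[f"{prefix}.ln1.g"], params[f"{prefix}.ln1.b"])
    hidden = (x @ params[f"{prefix}.ffn.W1"] + params[f"{prefix}.ffn.b1"]).relu()
    ff = hidden @ params[f"{prefix}.ffn.W2"] + params[f"{prefix}.ffn.b2"]
    return layer_norm(x + ff, params[f"{prefix}.ln2.g"], params[f"{prefix}.ln2.b"])


def encoder_stack(
    x: Tensor,
    params: dict[str, Tensor],
    prefix: str,
    layers: int,
    heads: int,
    mask: np.ndarray | None = None,
) -> Tensor:
    for layer in range(layers):
        x = transformer_layer(x, params, f"{prefix}.layer{layer}", heads, mask)
    return x


def length_buckets(lengths: np.ndarray,
                   edges: tuple[int, ...] = (8, 12, 16, 24, 32, 48, 64, 96, 128, 192, 256),
                   ) -> list[tuple[np.ndarray, int]]:
    """Group row indices by sequence length for padding-efficient batching.

    Attention cost grows with the square of the padded length, so encoding a
    few near-uniform buckets separately is much cheaper than padding every
    item to the global maximum.  Returns ``(row_indices, padded_length)``
    per non-empty bucket; row order within a bucket follows the input order.
    """
    lengths = np.asarray(lengths)
    out: list[tuple[np.ndarray, int]] = []
    lower = 0
    all_edges = list(edges)
    if lengths.max() > all_edges[-1]:
        all_edges.append(int(lengths.max()))
    for edge in all_edges:
        rows = np.flatnonzero((lengths > lower) & (lengths <= edge))
        if rows.size:
            out.append((rows, int(lengths[rows].max())))
        lower = edge
        if lower >= lengths.max():
            break
    return out


def masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over axis 1 of (B, T, d), counting only positions where mask is True."""
    weights = mask.astype(np.float64)
    counts = weights.sum(axis=1, keepdims=True)
    return (x * Tensor(weights[:, :, None])).sum(axis=1) / Tensor(counts)
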