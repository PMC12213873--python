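"""Cross-shape strip self-attention and the Cross Shape Transformer block.

Attention is restricted to non-overlapping horizontal or vertical bands
of width ``sw``: half of the heads attend within row bands, the other
half within column bands, so each position's receptive field is a cross
through its own row- and column-strips. With ``sw`` equal to the full
extent both groups see the whole grid and the operator degenerates to
vanilla multi-head attention — the oracle the tests use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor import Tensor, concat, pad2d, softmax
from .nn import LayerNorm, Linear, Mlp, Module

__all__ = ["StripPartition", "strip_partition", "strip_attention",
           "CrossShapeAttention", "CSTBlock"]


@dataclass(frozen=True)
class StripPartition:
    """Bookkeeping for an even division of an (H, W) grid into strips."""

    orientation: str            # "horizontal" | "vertical"
    sw: int
    shape: tuple[int, int]
    strips: list[np.ndarray] = field(repr=False)   # flat row-major indices

    @property
    def n_strips(self) -> int:
        return len(self.strips)


def strip_partition(shape: tuple[int, int], sw: int, orientation: str) -> StripPartition:
    """Divide an (H, W) grid into contiguous strips of width ``sw`` tokens.

    Horizontal strips are ``sw x W`` blocks ordered top-to-bottom;
    vertical strips are ``H x sw`` ordered left-to-right. The extent
    being divided must be a multiple of ``sw``.
    """
    H, W = shape
    if orientation not in ("horizontal", "vertical"):
        raise ValueError(f"unknown orientation {orientation!r}")
    extent = H if orientation == "horizontal" else W
    if sw < 1 or sw > extent:
        raise ValueError(f"strip width {sw} outside [1, {extent}]")
    if extent % sw:
        raise ValueError(f"extent {extent} not divisible by strip width {sw}")
    flat = np.arange(H * W).reshape(H, W)
    if orientation == "horizontal":
        strips = [flat[i * sw:(i + 1) * sw, :].ravel() for i in range(H // sw)]
    else:
        strips = [flat[:, j * sw:(j + 1) * sw].ravel() for j in range(W // sw)]
    return StripPartition(orientation, sw, (H, W), strips)


def strip_attention(strip_tokens, W_q, W_k, W_v):
    """Scaled dot-product self-attention inside one strip.

    ``strip_tokens`` is ``(n, C)``; the three head projections map C to
    d_k. Q, K and V are all computed from the same strip. Returns the
    ``(n, d_k)`` head output softmax(Q K^T / sqrt(d_k)) V.
    """
    x = strip_tokens if isinstance(strip_tokens, Tensor) else Tensor(np.asarray(strip_tokens))
    W_q, W_k, W_v = (w if isinstance(w, Tensor) else Tensor(np.asarray(w))
                     for w in (W_q, W_k, W_v))
    q, k, v = x @ W_q, x @ W_k, x @ W_v
    d_k = q.shape[-1]
    scores = (q @ k.transpose(1, 0)) * (1.0 / np.sqrt(d_k))
    return softmax(scores, axis=-1) @ v


def _band_attention(q: Tensor, k: Tensor, v: Tensor, sw: int, heads: int,
                    mask: np.ndarray | None) -> Tensor:
    """Multi-head attention within row bands of an (B, H, W, Ch) tensor.

    The caller transposes H/W to reuse this for column bands. ``mask``
    marks padded rows (True = padded) of length H.
    """
    B, H, W, Ch = q.shape
    d_k = Ch // heads
    M, n = H // sw, sw * W

    def bands(t: Tensor) -> Tensor:
        # (B, M, heads, n, d_k)
        return (t.reshape(B, M, n, heads, d_k).transpose(0, 1, 3, 2, 4))

    qb, kb, vb = bands(q), bands(k), bands(v)
    scores = (qb @ kb.transpose(0, 1, 2, 4, 3)) * (1.0 / np.sqrt(d_k))
    if mask is not None:
        key_pad = np.repeat(mask.reshape(M, sw), W, axis=1)      # (M, n)
        bias = np.where(key_pad, -1e9, 0.0).astype(scores.dtype)
        scores = scores + Tensor(bias[None, :, None, None, :])
    out = softmax(scores, axis=-1) @ vb
    return out.transpose(0, 1, 3, 2, 4).reshape(B, H, W, Ch)


class CrossShapeAttention(Module):
    """K-head attention with heads split between row and column strips.

    Heads 1..K/2 attend within horizontal strips of ``sw`` rows, heads
    K/2+1..K within vertical strips of ``sw`` columns; per-position head
    outputs are concatenated back to C channels and projected by W_O.
    Extents not divisible by ``sw`` are zero-padded, padded keys are
    masked out of the softmax and outputs cropped.
    """

    def __init__(self, rng: np.random.Generator, dim: int, heads: int, sw: int):
        if heads % 2:
            raise ValueError("head count must be even (two strip groups)")
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by {heads} heads")
        self.dim, self.heads, self.sw = dim, heads, sw
        self.W_q = Linear(rng, dim, dim)
        self.W_k = Linear(rng, dim, dim)
        self.W_v = Linear(rng, dim, dim)
        self.W_o = Linear(rng, dim, dim)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        if C != self.dim:
            raise ValueError(f"expected {self.dim} channels, got {C}")
        q, k, v = self.W_q(x), self.W_k(x), self.W_v(x)
        half = C // 2
        g = self.heads // 2
        sw_h, sw_w = min(self.sw, H), min(self.sw, W)

        def padded(t: Tensor, sw: int):
            hh = t.shape[1]
            rem = (-hh) % sw
            if rem == 0:
                return t, None
            mask = np.zeros(hh + rem, dtype=bool)
            mask[hh:] = True
            return pad2d(t, (0, rem), (0, 0)), mask

        qh, mask_h = padded(q[:, :, :, :half], sw_h)
        kh, _ = padded(k[:, :, :, :half], sw_h)
        vh, _ = padded(v[:, :, :, :half], sw_h)
        out_h = _band_attention(qh, kh, vh, sw_h, g, mask_h)[:, :H]

        def tr(t: Tensor) -> Tensor:
            return t.transpose(0, 2, 1, 3)

        qv, mask_v = padded(tr(q[:, :, :, half:]), sw_w)
        kv, _ = padded(tr(k[:, :, :, half:]), sw_w)
        vv, _ = padded(tr(v[:, :, :, half:]), sw_w)
        out_v = tr(_band_attention(qv, kv, vv, sw_w, g, mask_v)[:, :W])

        return self.W_o(concat([out_h, out_v], axis=-1))


class CSTBlock(Module):
    """Pre-norm transformer block with cross-shape attention.

        X_hat = CSA(LN(X)) + X
        X_out = MLP(LN(X_hat)) + X_hat

    The MLP has two layers with GELU; hidden width = mlp_ratio * C.
    With all weights zero both residual branches vanish and the block is
    the identity.
    """

    def __init__(self, rng: np.random.Generator, dim: int, heads: int, sw: int,
                 mlp_ratio: float = 4.0):
        self.norm1 = LayerNorm(dim)
        self.attn = CrossShapeAttention(rng, dim, heads, sw)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(rng, dim, int(round(mlp_ratio * dim)))

    def forward(self, x: Tensor) -> Tensor:
        x = self.attn(self.norm1(x)) + x
        return self.mlp(self.norm2(x)) + x
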