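"""Mamba-Transformer-Merge: coordinate-attention-style fusion of the two
encoder branches.

At each stage the transformer features E_T and the state-space features
E_M are concatenated and projected pointwise back to C channels, giving
the module input X. Directional average pooling compresses X into a
per-row profile Z_h (H x C) and a per-column profile Z_w (W x C); four
fully-connected branches reduce the concatenated profile to quarters
that are re-concatenated, split into a row half O_row and a column half
O_col, and combined by an outer product

    O[h, w, c] = O_row[h, c] * O_col[w, c],

so every channel slice of the attention map has matrix rank <= 1. The
map gates X through a sigmoid with a residual: out = X * sigmoid(O) + X,
which starts near identity for zero-initialised attention.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor, concat
from .nn import Linear, Module

__all__ = ["directional_pool", "MTMFusion"]


def directional_pool(x):
    """Mean-pool a ``(..., H, W, C)`` map along rows and columns.

    Returns ``(Z_h, Z_w)``: ``Z_h[..., h, c]`` is the mean of row h over
    all W columns; ``Z_w[..., w, c]`` the mean of column w over all H rows.
    """
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    z_h = t.mean(axis=-2)
    z_w = t.mean(axis=-3)
    if isinstance(x, Tensor):
        return z_h, z_w
    return z_h.numpy(), z_w.numpy()


class MTMFusion(Module):
    """Fuse two same-shape feature maps with rank-1 coordinate attention.

    ``gate_enabled=False`` disables the attention path entirely, leaving
    the pointwise 2C -> C fusion — the ablation baseline.
    """

    def __init__(self, rng: np.random.Generator, dim: int, gate_enabled: bool = True):
        if dim % 2:
            raise ValueError("channel count must be even (C/2 branch outputs)")
        self.dim = dim
        self.gate_enabled = gate_enabled
        self.fuse = Linear(rng, 2 * dim, dim)
        self.branches = [Linear(rng, 2 * dim, dim // 2) for _ in range(4)]

    def attention_map(self, z_h: Tensor, z_w: Tensor) -> Tensor:
        """Build the H x W x C rank-1 attention map from pooled profiles.

        For square maps the two profiles are concatenated along channels
        (length H = W, 2C channels); for H != W they are concatenated
        along the length axis instead and split back at H.
        """
        z_h, z_w = as_tensor(z_h), as_tensor(z_w)
        B, H, C = z_h.shape
        W = z_w.shape[1]
        if H == W:
            z = concat([z_h, z_w], axis=-1)               # (B, H, 2C)
        else:
            z = concat([z_h, z_w], axis=1)                # (B, H+W, C) -> pad channels
            z = concat([z, z], axis=-1)                   # positionwise 2C input
        f = concat([br(z).gelu() for br in self.branches], axis=-1)   # (B, L, 2C)
        if H == W:
            o_row = f[:, :, :C]
            o_col = f[:, :, C:]
        else:
            o_row = f[:, :H, :C]
            o_col = f[:, H:, C:]
        # outer product per channel: O[b,h,w,c] = o_row[b,h,c] * o_col[b,w,c]
        return o_row.reshape(B, H, 1, C) * o_col.reshape(B, 1, W, C)

    def forward(self, e_t: Tensor, e_m: Tensor) -> Tensor:
        if e_t.shape != e_m.shape:
            raise ValueError(f"branch shape mismatch: {e_t.shape} vs {e_m.shape}")
        x = self.fuse(concat([e_t, e_m], axis=-1))
        if not self.gate_enabled:
            return x
        z_h, z_w = directional_pool(x)
        o = self.attention_map(z_h, z_w)
        return x * o.sigmoid() + x
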