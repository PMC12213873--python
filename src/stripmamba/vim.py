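"""Tokenisation, positional embedding, stacked Vim blocks, patch merging.

A pyramid stage of the state-space encoder: the stage's feature map is
cut into P x P patches, flattened row-major (left-to-right, top-to-
bottom — also the forward scan order of the SSM), linearly projected to
D-dimensional tokens and given a learned, zero-initialised positional
table. After N bidirectional Vim blocks the tokens are merged back to a
(rows x cols x D) feature map in the same row-major order.

The class token of the classification formulation is supported behind a
flag but dropped in segmentation mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor import Tensor, concat, reflect_pad2d
from .nn import Linear, Module, ModuleList, Parameter
from .ssm import VimBlock

__all__ = ["TokenSequence", "PatchEmbed", "patch_merge", "VmeStage"]


@dataclass
class TokenSequence:
    """Tokens with their recorded spatial origin."""

    tokens: Tensor                 # (B, J[+1], D); cls token first if present
    grid_shape: tuple[int, int]    # (rows, cols) of the patch grid
    patch_size: int
    has_cls: bool = False

    def __post_init__(self):
        rows, cols = self.grid_shape
        expect = rows * cols + (1 if self.has_cls else 0)
        if self.tokens.shape[-2] != expect:
            raise ValueError(
                f"token count {self.tokens.shape[-2]} != rows*cols(+cls) {expect}")


class PatchEmbed(Module):
    """Flatten P x P patches and project them to D with a positional table.

    The positional table is owned per stage at a fixed grid resolution
    and zero-initialised, so at depth 0 it is the only source of spatial
    asymmetry. Inputs whose extent is not divisible by P are reflect-
    padded up to the next multiple (the stage crops after merging).
    """

    def __init__(self, rng: np.random.Generator, in_ch: int, embed_dim: int,
                 patch_size: int, grid_shape: tuple[int, int], use_cls: bool = False):
        self.in_ch, self.embed_dim, self.patch_size = in_ch, embed_dim, patch_size
        self.grid_shape = grid_shape
        self.use_cls = use_cls
        self.proj = Linear(rng, patch_size * patch_size * in_ch, embed_dim)
        J = grid_shape[0] * grid_shape[1]
        self.pos_embed = Parameter(np.zeros((J + (1 if use_cls else 0), embed_dim)))
        self.cls_token = Parameter(np.zeros(embed_dim)) if use_cls else None

    def set_identity(self) -> None:
        """Make tokenisation the identity (requires P=1 and D=C)."""
        if self.patch_size != 1 or self.in_ch != self.embed_dim:
            raise ValueError("identity tokenisation needs P=1 and D=C")
        self.proj.weight.data = np.eye(self.in_ch, dtype=self.proj.weight.dtype)
        self.proj.bias.data[:] = 0
        self.pos_embed.data[:] = 0

    def forward(self, x: Tensor) -> TokenSequence:
        B, H, W, C = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {C}")
        P = self.patch_size
        if H % P or W % P:
            x = reflect_pad2d(x, (0, (-H) % P), (0, (-W) % P))
            B, H, W, C = x.shape
        rows, cols = H // P, W // P
        if (rows, cols) != tuple(self.grid_shape):
            raise ValueError(
                f"grid {(rows, cols)} != stage grid {self.grid_shape}; "
                "each stage owns its positional table at a fixed resolution")
        # row-major patch order: (B, rows, cols, P*P*C)
        patches = (x.reshape(B, rows, P, cols, P, C)
                    .transpose(0, 1, 3, 2, 4, 5)
                    .reshape(B, rows * cols, P * P * C))
        tokens = self.proj(patches)
        if self.use_cls:
            cls = (self.cls_token + Tensor(np.zeros((B, 1, self.embed_dim),
                                                    dtype=tokens.dtype)))
            tokens = concat([cls, tokens], axis=1)
        tokens = tokens + self.pos_embed
        return TokenSequence(tokens, (rows, cols), P, has_cls=self.use_cls)


def patch_merge(seq: TokenSequence) -> Tensor:
    """Reshape a token sequence back to its (B, rows, cols, D) map.

    The class token, if present, is discarded; token order must match
    the row-major order used by :class:`PatchEmbed`.
    """
    rows, cols = seq.grid_shape
    t = seq.tokens
    if seq.has_cls:
        t = t[:, 1:, :]
    if t.shape[-2] != rows * cols:
        raise ValueError(f"token count {t.shape[-2]} != rows*cols {rows * cols}")
    return t.reshape(t.shape[0], rows, cols, t.shape[-1])


class VmeStage(Module):
    """One pyramid stage: tokenise -> N Vim blocks -> merge (and crop).

    With ``depth`` zero and identity tokenisation the stage is the
    identity map; the spatial size of the output always equals the
    input (padding introduced for non-divisible extents is cropped).
    """

    def __init__(self, rng: np.random.Generator, dim: int, depth: int,
                 grid_shape: tuple[int, int], patch_size: int = 1,
                 d_state: int = 16, expand: int = 2, conv_kernel: int = 4):
        self.dim = dim
        self.embed = PatchEmbed(rng, dim, dim, patch_size, grid_shape)
        self.blocks = ModuleList(
            VimBlock(rng, dim, d_state=d_state, expand=expand,
                     conv_kernel=conv_kernel) for _ in range(depth))

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        seq = self.embed(x)
        tokens = seq.tokens
        for blk in self.blocks:
            tokens = blk(tokens)
        out = patch_merge(TokenSequence(tokens, seq.grid_shape, seq.patch_size,
                                        seq.has_cls))
        P = self.embed.patch_size
        if P == 1 and out.shape[1:3] != (H, W):
            out = out[:, :H, :W, :]
        return out
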