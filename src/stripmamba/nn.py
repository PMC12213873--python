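"""Neural-network layers built on the autodiff core.

Feature maps are channel-last ``(B, H, W, C)``; linear layers act on the
trailing axis. Weight initialisation is drawn from a ``numpy.random.
Generator`` passed explicitly to every layer constructor, so building a
model with a fixed seed is fully reproducible.

Normalisation throughout the package is layer normalisation over the
channel axis: it is batch-size independent, which keeps small-batch
desk-scale training deterministic and comparable across batch sizes.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor, pad2d

__all__ = [
    "Module", "Parameter", "Linear", "LayerNorm", "Mlp",
    "Conv2d", "DepthwiseConv2d", "DepthwiseSeparableConv",
    "ModuleList", "zero_all_parameters", "count_parameters",
]

DTYPE = np.float32


class Parameter(Tensor):
    """A trainable tensor (requires_grad is always on)."""

    def __init__(self, data, name: str | None = None):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True, name=name)


class Module:
    """Minimal module container with parameter discovery by attribute walk."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = sorted(set(own) - set(state))
        extra = sorted(set(state) - set(own))
        if missing or extra:
            raise ValueError(f"state mismatch: missing={missing[:5]} extra={extra[:5]}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(DTYPE).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    std = math.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_features: int, out_features: int,
                 bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming(rng, in_features, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        y = x.reshape(-1, self.in_features) @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y.reshape(*lead, self.out_features)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.dim = dim
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        d = x - mu
        v = (d * d).mean(axis=-1, keepdims=True)
        xhat = d * ((v + self.eps) ** -0.5)
        return xhat * self.weight + self.bias


class Mlp(Module):
    """Two-layer perceptron with GELU, the transformer-block feedforward."""

    def __init__(self, rng, dim: int, hidden: int):
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class Conv2d(Module):
    """Same-padding stride-1 2-D convolution on ``(B, H, W, C)`` maps.

    Implemented as a sum of k*k shifted matmuls, which the tape
    differentiates without a dedicated im2col kernel.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 3, bias: bool = True):
        if kernel % 2 != 1:
            raise ValueError("odd kernel sizes only")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, fan_in, (kernel, kernel, in_ch, out_ch)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {C}")
        k = self.kernel
        p = k // 2
        xp = pad2d(x, (p, p), (p, p))
        out = None
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + H, j:j + W, :].reshape(-1, C)
                term = patch @ self.weight[i, j]
                out = term if out is None else out + term
        out = out.reshape(B, H, W, self.out_ch)
        if self.bias is not None:
            out = out + self.bias
        return out


class DepthwiseConv2d(Module):
    """Per-channel same-padding spatial convolution."""

    def __init__(self, rng, ch: int, kernel: int = 3, bias: bool = True):
        if kernel % 2 != 1:
            raise ValueError("odd kernel sizes only")
        self.ch, self.kernel = ch, kernel
        self.weight = Parameter(_kaiming(rng, kernel * kernel, (kernel, kernel, ch)))
        self.bias = Parameter(np.zeros(ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        k = self.kernel
        p = k // 2
        xp = pad2d(x, (p, p), (p, p))
        out = None
        for i in range(k):
            for j in range(k):
                term = xp[:, i:i + H, j:j + W, :] * self.weight[i, j]
                out = term if out is None else out + term
        from .tensor import add_macs
        add_macs(B * H * W * C * k * k)
        if self.bias is not None:
            out = out + self.bias
        return out


class DepthwiseSeparableConv(Module):
    """Depthwise k x k followed by pointwise 1 x 1, with norm + SiLU.

    Parameter count C_in*k^2 + C_in*C_out (+ biases) versus
    C_in*C_out*k^2 for a full convolution — the lightweight auxiliary
    stream of the backbone.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 3):
        self.depthwise = DepthwiseConv2d(rng, in_ch, kernel)
        self.pointwise = Linear(rng, in_ch, out_ch)
        self.norm = LayerNorm(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.pointwise(self.depthwise(x))).silu()


def zero_all_parameters(module: Module) -> None:
    """Set every trainable array (including norm scales) to zero.

    With all weights zero every residual block in this package reduces to
    the identity, which the tests exploit.
    """
    for p in module.parameters():
        p.data = np.zeros_like(p.data)


def count_parameters(module: Module) -> int:
    return sum(p.size for p in module.parameters())
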