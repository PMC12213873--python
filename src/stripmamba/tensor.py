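"""Reverse-mode automatic differentiation on numpy arrays.

This is the package's compute core: a small define-by-run tape. A
:class:`Tensor` wraps a ``numpy.ndarray``; every operation records the
parents it read and a closure that maps the output gradient to parent
gradients. :meth:`Tensor.backward` runs the tape in reverse topological
order. Layers and models in this package are built exclusively from the
primitives here, so a single scalar loss differentiates end to end.

Conventions
-----------
* Feature maps are channel-last: ``(B, H, W, C)``.
* Gradients accumulate into ``Tensor.grad`` as plain ndarrays.
* ``no_grad()`` disables taping (inference / profiling).
* ``mac_counter()`` makes dense linear-algebra ops (matmul and friends)
  accumulate multiply-accumulate counts, used by the profiler.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "is_grad_enabled",
    "mac_counter",
    "add_macs",
    "concat",
    "softmax",
    "pad2d",
    "reflect_pad2d",
    "resize_bilinear",
]

_GRAD_ENABLED = [True]
_MAC_STACK: list[list[int]] = []


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


@contextlib.contextmanager
def mac_counter():
    """Count multiply-accumulates of dense linear ops inside the block.

    Yields a one-element list; after the block, ``counter[0]`` holds the
    accumulated MAC count. Elementwise arithmetic, normalisation and
    activations are not counted — the convention is documented in the
    profiling module.
    """
    cell = [0]
    _MAC_STACK.append(cell)
    try:
        yield cell
    finally:
        _MAC_STACK.pop()


def add_macs(n: int) -> None:
    for cell in _MAC_STACK:
        cell[0] += int(n)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # ---- basic introspection -------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ---- graph plumbing ------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs here can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior gradients/graph references
                if node is not self:
                    node._backward = None
                    node._parents = ()
                    node.grad = None

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.data.ndim < 2 or other.data.ndim < 2:
            raise ValueError("matmul requires operands of ndim >= 2")
        out_data = np.matmul(self.data, other.data)
        if _MAC_STACK:
            add_macs(out_data.size * self.data.shape[-1])

        def backward(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # ---- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape
        advanced = isinstance(idx, np.ndarray) or (
            isinstance(idx, tuple) and any(isinstance(i, np.ndarray) for i in idx))

        def backward(g):
            full = np.zeros(shape, dtype=g.dtype)
            if advanced:
                np.add.at(full, idx, g)
            else:
                full[idx] = g
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # ---- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy() if np.ndim(g) else np.full(shape, g, dtype=self.dtype))
                return
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(a % len(shape) for a in ax)
                g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, shape).astype(self.dtype, copy=True))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def var(self, axis=-1, keepdims: bool = True):
        mu = self.mean(axis=axis, keepdims=True)
        d = self - mu
        return (d * d).mean(axis=axis, keepdims=keepdims)

    # ---- elementwise nonlinearities ------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0)

        def backward(g):
            self._accum(g * (self.data > 0))

        return Tensor._make(out_data, (self,), backward)

    def silu(self):
        s = _sigmoid(self.data)
        out_data = self.data * s

        def backward(g):
            self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        # tanh approximation of GELU
        c = math.sqrt(2.0 / math.pi)
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            dg = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
            self._accum(g * dg)

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            self._accum(g * _sigmoid(self.data))

        return Tensor._make(out_data, (self,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---- free functions -----------------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))  # detached stabiliser
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def pad2d(x: Tensor, pad_h: tuple[int, int], pad_w: tuple[int, int],
          value: float = 0.0) -> Tensor:
    """Zero/constant-pad the spatial axes of a ``(B, H, W, C)`` tensor."""
    (t, b), (l, r) = pad_h, pad_w
    B, H, W, C = x.shape
    out_data = np.full((B, H + t + b, W + l + r, C), value, dtype=x.dtype)
    out_data[:, t:t + H, l:l + W, :] = x.data

    def backward(g):
        x._accum(g[:, t:t + H, l:l + W, :])

    return Tensor._make(out_data, (x,), backward)


def reflect_pad2d(x: Tensor, pad_h: tuple[int, int], pad_w: tuple[int, int]) -> Tensor:
    """Reflect-pad the spatial axes of a ``(B, H, W, C)`` tensor."""
    (t, b), (l, r) = pad_h, pad_w
    B, H, W, C = x.shape
    ih = _reflect_index(H, t, b)
    iw = _reflect_index(W, l, r)
    out_data = x.data[:, ih][:, :, iw]

    def backward(g):
        gx = np.zeros((B, H, W, C), dtype=g.dtype)
        # scatter-add along each padded axis in turn
        tmp = np.zeros((B, H, g.shape[2], C), dtype=g.dtype)
        np.add.at(tmp, (slice(None), ih), g)
        np.add.at(gx, (slice(None), slice(None), iw), tmp)
        x._accum(gx)

    return Tensor._make(out_data, (x,), backward)


def _reflect_index(n: int, before: int, after: int) -> np.ndarray:
    idx = np.arange(-before, n + after)
    period = max(2 * n - 2, 1)
    idx = np.mod(idx, period)
    idx = np.where(idx >= n, period - idx, idx)
    return idx


def _bilinear_matrix(n_out: int, n_in: int, dtype=np.float64) -> np.ndarray:
    """Row-stochastic interpolation matrix, half-pixel-centre convention."""
    R = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        R[:, 0] = 1.0
        return R
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(math.floor(src))
        hi = min(lo + 1, n_in - 1)
        w = src - lo
        R[i, lo] += 1.0 - w
        R[i, hi] += w
    return R


_BILIN_CACHE: dict[tuple[int, int, str], np.ndarray] = {}


def _bilin(n_out: int, n_in: int, dtype) -> np.ndarray:
    key = (n_out, n_in, np.dtype(dtype).str)
    if key not in _BILIN_CACHE:
        _BILIN_CACHE[key] = _bilinear_matrix(n_out, n_in).astype(dtype)
    return _BILIN_CACHE[key]


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of a ``(B, H, W, C)`` tensor (half-pixel centres)."""
    B, H, W, C = x.shape
    Rh = _bilin(out_h, H, x.dtype)
    Rw = _bilin(out_w, W, x.dtype)
    out_data = np.einsum("ph,bhwc->bpwc", Rh, x.data, optimize=True)
    out_data = np.einsum("qw,bpwc->bpqc", Rw, out_data, optimize=True)
    if _MAC_STACK:
        add_macs(B * out_h * W * C * H + B * out_h * out_w * C * W)

    def backward(g):
        gx = np.einsum("qw,bpqc->bpwc", Rw, g, optimize=True)
        gx = np.einsum("ph,bpwc->bhwc", Rh, gx, optimize=True)
        x._accum(gx.astype(x.dtype))

    return Tensor._make(out_data, (x,), backward)
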