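"""Selective state-space scan and the bidirectional Vim block.

The selective SSM is the linear recurrence

    h_t = A_bar_t * h_{t-1} + B_bar_t * x_t
    y_t = C_t . h_t + D * x_t,          h_0 = 0

with input-dependent ("selective") B_t, C_t and step size Delta_t, and a
diagonal negative evolution matrix A. Discretisation is zero-order hold
on A with the simplified Euler rule for B:

    A_bar = exp(Delta * A),   B_bar = Delta * B.

Delta passes through a softplus so it is strictly positive; D is an
unconstrained per-channel skip coefficient.

The sequential scan (and its adjoint) are compiled with numba; a naive
step-by-step numpy loop serves as the oracle in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .tensor import Tensor, add_macs, as_tensor, concat, is_grad_enabled
from .nn import DTYPE, LayerNorm, Linear, Module, Parameter

__all__ = [
    "positivity_transform",
    "discretize",
    "selective_scan",
    "SSMDirectionParams",
    "VimBlock",
]


# ---------------------------------------------------------------------------
# spec'd functional primitives
# ---------------------------------------------------------------------------

def positivity_transform(raw_delta):
    """Softplus map producing strictly positive step sizes.

    Accepts a numpy array (returns an array) or a :class:`Tensor`
    (returns a Tensor on the tape). Raises on non-finite input.
    """
    floor = 1e-20  # softplus underflows to 0.0 below ~-87; keep output > 0
    if isinstance(raw_delta, Tensor):
        if not np.all(np.isfinite(raw_delta.data)):
            raise ValueError("non-finite values in raw delta")
        y = raw_delta.softplus()
        return y + Tensor(np.maximum(floor - y.data, 0.0))
    x = np.asarray(raw_delta, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in raw delta")
    return np.maximum(np.logaddexp(0.0, x), floor)


def discretize(delta, A, B):
    """Zero-order-hold discretisation: ``A_bar = exp(delta*A)``, ``B_bar = delta*B``.

    ``delta`` must be strictly positive; with ``A <= 0`` the returned
    ``A_bar`` lies in (0, 1].
    """
    delta = np.asarray(delta, dtype=np.float64)
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if np.any(delta <= 0):
        raise ValueError("delta must be strictly positive")
    return np.exp(delta * A), delta * B


# ---------------------------------------------------------------------------
# compiled scan kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _scan_fwd(u, delta, A, Bm, Cm, D, y, hs, save_h):
    Bsz, L, E = u.shape
    S = A.shape[1]
    for b in range(Bsz):
        h = np.zeros((E, S), dtype=u.dtype)
        for t in range(L):
            for e in range(E):
                dte = delta[b, t, e]
                ue = u[b, t, e]
                acc = 0.0
                for s in range(S):
                    ab = math.exp(dte * A[e, s])
                    hn = ab * h[e, s] + dte * Bm[b, t, s] * ue
                    h[e, s] = hn
                    acc += Cm[b, t, s] * hn
                y[b, t, e] = acc + D[e] * ue
            if save_h:
                for e in range(E):
                    for s in range(S):
                        hs[b, t, e, s] = h[e, s]


@njit(cache=True)
def _scan_bwd(u, delta, A, Bm, Cm, D, hs, gy, gu, gdelta, gA, gBm, gCm, gD):
    Bsz, L, E = u.shape
    S = A.shape[1]
    for b in range(Bsz):
        dh = np.zeros((E, S), dtype=u.dtype)
        for t in range(L - 1, -1, -1):
            for e in range(E):
                gye = gy[b, t, e]
                ue = u[b, t, e]
                dte = delta[b, t, e]
                gD[e] += gye * ue
                gu_acc = D[e] * gye
                gd_acc = 0.0
                for s in range(S):
                    dhes = dh[e, s] + gye * Cm[b, t, s]
                    gCm[b, t, s] += gye * hs[b, t, e, s]
                    hprev = hs[b, t - 1, e, s] if t > 0 else 0.0
                    ab = math.exp(dte * A[e, s])
                    gA[e, s] += dhes * ab * dte * hprev
                    gd_acc += dhes * (ab * A[e, s] * hprev + Bm[b, t, s] * ue)
                    gBm[b, t, s] += dhes * dte * ue
                    gu_acc += dhes * dte * Bm[b, t, s]
                    dh[e, s] = dhes * ab
                gdelta[b, t, e] = gd_acc
                gu[b, t, e] = gu_acc


def _scan_op(u: Tensor, delta: Tensor, A: Tensor, Bm: Tensor, Cm: Tensor,
             D: Tensor) -> Tensor:
    """Autodiff node around the compiled scan. Shapes:

    u, delta: (B, L, E); A: (E, S); Bm, Cm: (B, L, S); D: (E,).
    """
    Bsz, L, E = u.shape
    S = A.shape[1]
    need_grad = is_grad_enabled() and any(
        t.requires_grad for t in (u, delta, A, Bm, Cm, D))
    y = np.empty_like(u.data)
    hs = (np.empty((Bsz, L, E, S), dtype=u.data.dtype) if need_grad
          else np.empty((1, 1, 1, 1), dtype=u.data.dtype))
    _scan_fwd(u.data, delta.data, A.data, Bm.data, Cm.data, D.data,
              y, hs, need_grad)
    # per step per (e,s): A_bar*h, dte*B*u (2), C*h  -> ~4 MACs; + skip
    add_macs(Bsz * L * E * (4 * S + 1))

    def backward(g):
        gu = np.zeros_like(u.data)
        gdelta = np.zeros_like(delta.data)
        gA = np.zeros_like(A.data)
        gBm = np.zeros_like(Bm.data)
        gCm = np.zeros_like(Cm.data)
        gD = np.zeros_like(D.data)
        _scan_bwd(u.data, delta.data, A.data, Bm.data, Cm.data, D.data,
                  hs, np.ascontiguousarray(g), gu, gdelta, gA, gBm, gCm, gD)
        u._accum(gu)
        delta._accum(gdelta)
        A._accum(gA)
        Bm._accum(gBm)
        Cm._accum(gCm)
        D._accum(gD)

    return Tensor._make(y, (u, delta, A, Bm, Cm, D), backward)


def selective_scan(u, delta, A, B, C, D):
    """Run the selective scan.

    Parameters may be numpy arrays or Tensors. ``u`` and ``delta`` are
    ``(L, E)`` or ``(B, L, E)``; ``A`` is ``(E, S)`` (negative, diagonal
    per channel-state pair); ``B`` and ``C`` are per-step ``(.., L, S)``;
    ``D`` is ``(E,)``. Returns the same container type as ``u`` with the
    same leading shape. The recurrence is causal: y_t depends only on
    x_1..x_t of its own direction.
    """
    tensors = [u, delta, A, B, C, D]
    as_np = not any(isinstance(t, Tensor) for t in tensors)
    u, delta, A, B, C, D = (as_tensor(np.asarray(t, dtype=np.float64) if as_np else t)
                            for t in tensors)
    squeeze = u.ndim == 2
    if squeeze:
        u = u.reshape(1, *u.shape)
        delta = delta.reshape(1, *delta.shape)
        B = B.reshape(1, *B.shape)
        C = C.reshape(1, *C.shape)
    if u.shape != delta.shape:
        raise ValueError(f"u/delta shape mismatch: {u.shape} vs {delta.shape}")
    if A.shape[0] != u.shape[2] or D.shape[0] != u.shape[2]:
        raise ValueError("channel dimension mismatch between params and sequence")
    if B.shape[:2] != u.shape[:2] or C.shape[:2] != u.shape[:2] or \
            B.shape[2] != A.shape[1] or C.shape[2] != A.shape[1]:
        raise ValueError("B/C shape inconsistent with sequence and state size")
    if np.any(delta.data <= 0):
        raise ValueError("delta must be strictly positive")
    y = _scan_op(u, delta, A, B, C, D)
    if squeeze:
        y = y.reshape(*y.shape[1:])
    return y.numpy() if as_np else y


# ---------------------------------------------------------------------------
# Vim block
# ---------------------------------------------------------------------------

def _softplus_inverse(y: float) -> float:
    return math.log(math.expm1(y))


class SSMDirectionParams(Module):
    """One direction's selective-SSM parameters.

    Holds the learned log-evolution matrix (A = -exp(A_log) < 0), the
    skip coefficient D, the causal depthwise conv kernel, and the linear
    maps producing input-dependent B, C and (raw) Delta from the
    convolved sequence. Forward and backward directions each own an
    independent instance.
    """

    def __init__(self, rng: np.random.Generator, d_inner: int, d_state: int,
                 conv_kernel: int):
        self.d_inner, self.d_state, self.conv_kernel = d_inner, d_state, conv_kernel
        # S4D-real style init: A = -(1..d_state) per inner channel
        self.A_log = Parameter(np.log(np.tile(np.arange(1, d_state + 1, dtype=np.float64),
                                              (d_inner, 1))))
        self.D_skip = Parameter(np.ones(d_inner))
        self.conv_weight = Parameter(_conv_init(rng, conv_kernel, d_inner))
        self.conv_bias = Parameter(np.zeros(d_inner))
        self.W_B = Linear(rng, d_inner, d_state, bias=False)
        self.W_C = Linear(rng, d_inner, d_state, bias=False)
        self.W_delta = Linear(rng, d_inner, d_inner)
        # step sizes start log-uniform in [1e-3, 1e-1], the usual range
        dt = np.exp(rng.uniform(math.log(1e-3), math.log(1e-1), size=d_inner))
        self.W_delta.bias.data = np.array(
            [_softplus_inverse(v) for v in dt], dtype=DTYPE)

    @property
    def A(self) -> Tensor:
        return -self.A_log.exp()

    def causal_conv(self, x: Tensor) -> Tensor:
        """Left-padded depthwise 1-D convolution over the token axis."""
        Bsz, L, E = x.shape
        k = self.conv_kernel
        zeros = Tensor(np.zeros((Bsz, k - 1, E), dtype=x.dtype))
        xp = concat([zeros, x], axis=1)
        out = None
        for i in range(k):
            term = xp[:, i:i + L, :] * self.conv_weight[i]
            out = term if out is None else out + term
        add_macs(Bsz * L * E * k)
        return out + self.conv_bias

    def scan(self, x: Tensor) -> Tensor:
        """conv -> SiLU -> (B, C, Delta) -> softplus -> selective scan."""
        x1 = self.causal_conv(x).silu()
        Bm = self.W_B(x1)
        Cm = self.W_C(x1)
        delta = positivity_transform(self.W_delta(x1))
        return _scan_op(x1, delta, self.A, Bm, Cm, self.D_skip)


def _conv_init(rng, k, ch):
    std = 1.0 / math.sqrt(k)
    return rng.uniform(-std, std, size=(k, ch))


class VimBlock(Module):
    """Bidirectional Mamba block with residual connection.

    Pipeline: LN -> linear x-path and z-path -> per direction
    {causal depthwise conv + SiLU + selective scan, the backward
    direction on the reversed token order} -> each direction gated by
    SiLU(z) -> directions summed -> output projection -> residual add.
    """

    def __init__(self, rng: np.random.Generator, d_model: int, d_state: int = 16,
                 expand: int = 2, conv_kernel: int = 4):
        self.d_model = d_model
        self.d_inner = expand * d_model
        self.norm = LayerNorm(d_model)
        self.W_in = Linear(rng, d_model, 2 * self.d_inner)
        self.fwd = SSMDirectionParams(rng, self.d_inner, d_state, conv_kernel)
        self.bwd = SSMDirectionParams(rng, self.d_inner, d_state, conv_kernel)
        self.W_out = Linear(rng, self.d_inner, d_model)

    def forward(self, tokens: Tensor) -> Tensor:
        if tokens.shape[-1] != self.d_model:
            raise ValueError(f"token width {tokens.shape[-1]} != d_model {self.d_model}")
        squeeze = tokens.ndim == 2
        t = tokens.reshape(1, *tokens.shape) if squeeze else tokens
        xz = self.W_in(self.norm(t))
        x = xz[:, :, :self.d_inner]
        z = xz[:, :, self.d_inner:]
        gate = z.silu()
        y_f = self.fwd.scan(x)
        y_b = self.bwd.scan(x[:, ::-1, :])[:, ::-1, :]
        y = y_f * gate + y_b * gate
        out = self.W_out(y)
        out = out + t
        return out.reshape(*tokens.shape) if squeeze else out
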