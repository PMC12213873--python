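"""Selective-scan oracle equivalence, causality, stability; Vim block
residual/symmetry properties."""

import numpy as np
import pytest

from stripmamba.nn import zero_all_parameters
from stripmamba.ssm import (SSMDirectionParams, VimBlock, discretize,
                            positivity_transform, selective_scan)
from stripmamba.tensor import Tensor


def naive_scan(u, delta, A, B, C, D):
    """Independent step-by-step recurrence oracle."""
    L, E = u.shape
    S = A.shape[1]
    h = np.zeros((E, S))
    ys = []
    for t in range(L):
        A_bar = np.exp(delta[t][:, None] * A)
        h = A_bar * h + (delta[t][:, None] * B[t][None, :]) * u[t][:, None]
        ys.append(h @ C[t] + D * u[t])
    return np.array(ys)


def random_instance(rng, L, E, S):
    u = rng.normal(size=(L, E))
    delta = np.exp(rng.normal(size=(L, E)) * 0.5) * 0.05
    A = -np.exp(rng.normal(size=(E, S)))
    B = rng.normal(size=(L, S))
    C = rng.normal(size=(L, S))
    D = rng.normal(size=E)
    return u, delta, A, B, C, D


class TestPositivityTransform:
    def test_softplus_closed_forms(self):
        assert np.isclose(positivity_transform(np.array([0.0]))[0], np.log(2))
        assert np.isclose(positivity_transform(np.array([40.0]))[0], 40.0)
        small = positivity_transform(np.array([-1000.0]))[0]
        assert 0 < small < 1e-10

    def test_monotone_and_smooth(self, rng):
        x = np.sort(rng.normal(size=50) * 5)
        y = positivity_transform(x)
        assert (np.diff(y) > 0).all() and (y > 0).all()

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            positivity_transform(np.array([np.nan]))


class TestDiscretize:
    def test_closed_forms(self):
        A_bar, B_bar = discretize(np.array(0.5), np.array(-2.0), np.array(1.0))
        assert np.isclose(A_bar, np.exp(-1.0))
        assert np.isclose(B_bar, 0.5)
        A_bar, _ = discretize(np.array(0.7), np.array(0.0), np.array(1.0))
        assert A_bar == 1.0

    def test_small_delta_freezes_state(self):
        A_bar, B_bar = discretize(np.array(1e-12), np.array(-3.0), np.array(2.0))
        assert np.isclose(A_bar, 1.0) and np.isclose(B_bar, 0.0, atol=1e-10)

    def test_range_contract(self, rng):
        delta = np.exp(rng.normal(size=20)) * 0.1
        A = -np.exp(rng.normal(size=20))
        A_bar, _ = discretize(delta, A, np.ones(20))
        assert ((A_bar > 0) & (A_bar < 1)).all()

    def test_rejects_nonpositive_delta(self):
        with pytest.raises(ValueError):
            discretize(np.array([0.0]), np.array([-1.0]), np.array([1.0]))


class TestSelectiveScan:
    def test_matches_naive_loop_oracle(self, rng):
        for _ in range(30):
            L = int(rng.integers(1, 65))
            E = int(rng.integers(1, 9))
            S = int(rng.integers(1, 9))
            inst = random_instance(rng, L, E, S)
            y = selective_scan(*inst)
            y0 = naive_scan(*inst)
            scale = np.abs(y0).max() + 1e-12
            assert np.abs(y - y0).max() / scale < 1e-5

    def test_zero_input_zero_output(self, rng):
        u, delta, A, B, C, D = random_instance(rng, 12, 3, 4)
        y = selective_scan(np.zeros_like(u), delta, A, B, C, D)
        assert np.allclose(y, 0.0)

    def test_single_step_unrolls(self, rng):
        u, delta, A, B, C, D = random_instance(rng, 1, 3, 4)
        y = selective_scan(u, delta, A, B, C, D)
        B_bar = delta[0][:, None] * B[0][None, :]
        expect = (B_bar * u[0][:, None]) @ C[0] + D * u[0]
        assert np.allclose(y[0], expect)

    def test_causality_under_perturbation(self, rng):
        u, delta, A, B, C, D = random_instance(rng, 20, 3, 4)
        y = selective_scan(u, delta, A, B, C, D)
        t0 = 12
        u2 = u.copy()
        u2[t0] += 3.0
        y2 = selective_scan(u2, delta, A, B, C, D)
        assert np.array_equal(y[:t0], y2[:t0])
        assert not np.allclose(y[t0:], y2[t0:])

    def test_state_stays_bounded_with_stable_dynamics(self, rng):
        # |h_t| <= max|B_bar*x| / (1 - max A_bar) for A < 0, bounded input
        for _ in range(5):
            u, delta, A, B, C, D = random_instance(rng, 64, 2, 3)
            A_bar = np.exp(delta[:, :, None] * A[None])
            B_bar = delta[:, :, None] * B[:, None, :]
            drive = np.abs(B_bar * u[:, :, None]).max()
            bound = drive / (1.0 - A_bar.max())
            h = np.zeros((2, 3))
            for t in range(64):
                h = A_bar[t] * h + B_bar[t] * u[t][:, None]
                assert np.abs(h).max() <= bound + 1e-9

    def test_dimension_mismatch_rejected(self, rng):
        u, delta, A, B, C, D = random_instance(rng, 8, 3, 4)
        with pytest.raises(ValueError):
            selective_scan(u, delta, A[:2], B, C, D)
        with pytest.raises(ValueError):
            selective_scan(u, delta, A, B[:, :3], C, D)


class TestVimBlock:
    def test_zero_weights_reduce_to_identity(self, rng):
        blk = VimBlock(np.random.default_rng(0), d_model=6, d_state=4)
        zero_all_parameters(blk)
        x = rng.normal(size=(2, 9, 6)).astype(np.float32)
        assert np.array_equal(blk(Tensor(x)).numpy(), x)

    def test_shape_preserved(self, rng):
        blk = VimBlock(np.random.default_rng(1), d_model=6, d_state=4)
        x = rng.normal(size=(11, 6)).astype(np.float32)
        assert blk(Tensor(x)).shape == (11, 6)

    def test_full_reversal_covariance_with_tied_directions(self, rng):
        blk = VimBlock(np.random.default_rng(2), d_model=6, d_state=4)
        blk.bwd.load_state_dict(blk.fwd.state_dict())
        x = rng.normal(size=(1, 13, 6)).astype(np.float32)
        y_rev = blk(Tensor(x[:, ::-1].copy())).numpy()
        rev_y = blk(Tensor(x)).numpy()[:, ::-1]
        assert np.allclose(y_rev, rev_y, atol=1e-6)

    def test_not_covariant_under_arbitrary_permutation(self, rng):
        blk = VimBlock(np.random.default_rng(2), d_model=6, d_state=4)
        blk.bwd.load_state_dict(blk.fwd.state_dict())
        x = rng.normal(size=(1, 13, 6)).astype(np.float32)
        perm = np.random.default_rng(5).permutation(13)
        y_perm = blk(Tensor(x[:, perm].copy())).numpy()
        perm_y = blk(Tensor(x)).numpy()[:, perm]
        assert not np.allclose(y_perm, perm_y, atol=1e-4)

    def test_direction_parameters_are_independent(self):
        blk = VimBlock(np.random.default_rng(3), d_model=6, d_state=4)
        fwd = blk.fwd.state_dict()
        bwd = blk.bwd.state_dict()
        assert any(not np.array_equal(fwd[k], bwd[k]) for k in fwd)

    def test_direction_params_satisfy_invariants(self):
        p = SSMDirectionParams(np.random.default_rng(4), d_inner=8, d_state=5,
                               conv_kernel=4)
        assert (-np.exp(p.A_log.data) < 0).all()
        x = Tensor(np.random.default_rng(0).normal(size=(1, 6, 8)).astype(np.float32))
        delta = positivity_transform(p.W_delta(p.causal_conv(x).silu()))
        assert (delta.numpy() > 0).all()
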