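"""Strip partitioning, strip attention oracles, and the CST block."""

import numpy as np
import pytest

from stripmamba.csa import (CrossShapeAttention, CSTBlock, strip_attention,
                            strip_partition)
from stripmamba.nn import zero_all_parameters
from stripmamba.tensor import Tensor


def brute_force_attention(x, Wq, Wk, Wv, mask=None):
    q, k, v = x @ Wq, x @ Wk, x @ Wv
    s = (q @ k.T) / np.sqrt(Wq.shape[1])
    if mask is not None:
        s = s + mask
    a = np.exp(s - s.max(-1, keepdims=True))
    a /= a.sum(-1, keepdims=True)
    return a @ v


class TestStripPartition:
    def test_counts_and_coverage(self):
        p = strip_partition((4, 6), 2, "horizontal")
        assert p.n_strips == 2
        assert all(len(s) == 2 * 6 for s in p.strips)
        covered = np.sort(np.concatenate(p.strips))
        assert np.array_equal(covered, np.arange(24))

    def test_full_extent_single_strip(self):
        p = strip_partition((4, 4), 4, "horizontal")
        assert p.n_strips == 1 and len(p.strips[0]) == 16

    def test_vertical_orientation(self):
        p = strip_partition((3, 6), 3, "vertical")
        assert p.n_strips == 2
        assert all(len(s) == 9 for s in p.strips)

    def test_reconstruction_is_a_bijection(self):
        p = strip_partition((6, 4), 3, "horizontal")
        grid = np.arange(24).reshape(6, 4)
        rebuilt = np.full(24, -1)
        for s in p.strips:
            rebuilt[s] = grid.ravel()[s]
        assert np.array_equal(rebuilt.reshape(6, 4), grid)

    @pytest.mark.parametrize("sw", [0, 5, -1])
    def test_bad_strip_width_rejected(self, sw):
        with pytest.raises(ValueError):
            strip_partition((4, 4), sw, "horizontal")


class TestStripAttention:
    def test_single_token_returns_its_value(self, rng):
        x = rng.normal(size=(1, 6))
        Wq, Wk, Wv = (rng.normal(size=(6, 3)) for _ in range(3))
        out = strip_attention(x, Wq, Wk, Wv).numpy()
        assert np.allclose(out, x @ Wv)

    def test_equal_keys_average_values(self, rng):
        x = rng.normal(size=(5, 6))
        Wq, Wv = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        Wk = np.zeros((6, 3))           # all keys equal -> uniform softmax
        out = strip_attention(x, Wq, Wk, Wv).numpy()
        assert np.allclose(out, np.tile((x @ Wv).mean(0), (5, 1)))

    def test_equals_masked_full_grid_attention(self, rng):
        H, W, C, sw = 6, 4, 5, 2
        x = rng.normal(size=(H * W, C))
        Wq, Wk, Wv = (rng.normal(size=(C, 3)) for _ in range(3))
        part = strip_partition((H, W), sw, "horizontal")
        for s in part.strips:
            local = strip_attention(x[s], Wq, Wk, Wv).numpy()
            mask = np.full((H * W, H * W), -1e30)
            mask[np.ix_(s, s)] = 0.0
            full = brute_force_attention(x, Wq, Wk, Wv, mask)
            assert np.allclose(local, full[s], atol=1e-10)


class TestCrossShapeAttention:
    def _f64(self, mod):
        for p in mod.parameters():
            p.data = p.data.astype(np.float64)
        return mod

    def test_full_extent_equals_vanilla_mha(self, rng):
        H = W = 6
        C, K = 8, 4
        csa = self._f64(CrossShapeAttention(np.random.default_rng(0), C, K, sw=H))
        x = rng.normal(size=(1, H, W, C))
        out = csa(Tensor(x)).numpy()
        xf = x.reshape(1, H * W, C)
        q = xf @ csa.W_q.weight.data + csa.W_q.bias.data
        k = xf @ csa.W_k.weight.data + csa.W_k.bias.data
        v = xf @ csa.W_v.weight.data + csa.W_v.bias.data
        dk = C // K
        heads = []
        for h in range(K):
            sl = slice(h * dk, (h + 1) * dk)
            s = (q[..., sl] @ k[..., sl].transpose(0, 2, 1)) / np.sqrt(dk)
            a = np.exp(s - s.max(-1, keepdims=True))
            a /= a.sum(-1, keepdims=True)
            heads.append(a @ v[..., sl])
        ref = (np.concatenate(heads, -1) @ csa.W_o.weight.data
               + csa.W_o.bias.data).reshape(1, H, W, C)
        rel = np.abs(out - ref).max() / (np.abs(ref).max() + 1e-12)
        assert rel < 1e-10

    def test_shape_preserved_including_padded_extents(self, rng):
        csa = CrossShapeAttention(np.random.default_rng(1), 8, 4, sw=3)
        for H, W in [(6, 6), (7, 5), (3, 3)]:
            x = rng.normal(size=(2, H, W, 8)).astype(np.float32)
            assert csa(Tensor(x)).shape == (2, H, W, 8)

    def test_horizontal_heads_are_strip_local(self, rng):
        # perturbing one horizontal strip changes horizontal-head outputs
        # only inside that strip (vertical heads may change anywhere)
        csa = CrossShapeAttention(np.random.default_rng(2), 8, 4, sw=2)
        x = rng.normal(size=(1, 6, 4, 8)).astype(np.float64)
        x2 = x.copy()
        x2[0, 2:4] += 1.0                      # second strip
        csa = self._f64(csa)
        csa.W_o.weight.data = np.eye(8)        # observe heads directly
        csa.W_o.bias.data[:] = 0
        a = csa(Tensor(x)).numpy()[..., :4]    # horizontal-head channels
        b = csa(Tensor(x2)).numpy()[..., :4]
        assert np.array_equal(a[0, 0:2], b[0, 0:2])
        assert np.array_equal(a[0, 4:6], b[0, 4:6])
        assert not np.allclose(a[0, 2:4], b[0, 2:4])

    def test_attention_cost_scales_linearly_with_strip_width(self):
        # score count = (H/sw) * (sw*W)^2 per head group: linear in sw
        H = W = 12
        counts = []
        for sw in (2, 4):
            part = strip_partition((H, W), sw, "horizontal")
            counts.append(sum(len(s) ** 2 for s in part.strips))
        assert counts[1] == 2 * counts[0]

    def test_odd_head_count_rejected(self):
        with pytest.raises(ValueError):
            CrossShapeAttention(np.random.default_rng(0), 9, 3, sw=2)


class TestCSTBlock:
    def test_zero_weights_identity(self, rng):
        blk = CSTBlock(np.random.default_rng(0), dim=8, heads=2, sw=3)
        zero_all_parameters(blk)
        x = rng.normal(size=(2, 5, 7, 8)).astype(np.float32)
        assert np.array_equal(blk(Tensor(x)).numpy(), x)

    def test_shape_preserved(self, rng):
        blk = CSTBlock(np.random.default_rng(1), dim=8, heads=4, sw=2)
        x = rng.normal(size=(1, 6, 6, 8)).astype(np.float32)
        assert blk(Tensor(x)).shape == x.shape

    def test_input_gradient_matches_finite_differences(self, rng):
        blk = CSTBlock(np.random.default_rng(2), dim=8, heads=2, sw=2)
        for p in blk.parameters():
            p.data = p.data.astype(np.float64)
        x = rng.normal(size=(1, 4, 4, 8))
        w = rng.normal(size=(1, 4, 4, 8))

        def f(a):
            return (blk(Tensor(a)) * Tensor(w)).sum().item()

        t = Tensor(x.copy(), requires_grad=True)
        (blk(t) * Tensor(w)).sum().backward()
        eps = 1e-6
        idx = [(0, i, j, c) for i in (0, 3) for j in (1, 2) for c in (0, 5)]
        for i in idx:
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            gn = (f(xp) - f(xm)) / (2 * eps)
            assert abs(gn - t.grad[i]) < 1e-4
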