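"""Backbone assembly: shapes, identities, profiling, checkpoints."""

import numpy as np
import pytest

from stripmamba.model import (ModelConfig, SMOKE_CONFIG, SegModel, Downsample,
                              load_checkpoint, profile, save_checkpoint)
from stripmamba.nn import (DepthwiseSeparableConv, count_parameters,
                           zero_all_parameters)
from stripmamba.tensor import Tensor, no_grad

TINY = dict(channels=(4, 8, 12, 16, 20), depths_cst=(1, 0, 0, 0, 0),
            depths_vme=(1, 0, 0, 0, 0), heads=(2, 2, 2, 2, 2),
            input_size=32, d_state=4)


def tiny_model(seed=0, **over):
    return SegModel(ModelConfig(**{**TINY, **over}), seed=seed)


class TestConfig:
    def test_defaults_are_the_calibrated_schedule(self):
        cfg = ModelConfig()
        assert cfg.channels == (32, 64, 128, 256, 512)
        assert cfg.sw == 3 and cfg.out_channels == 1

    @pytest.mark.parametrize("bad", [
        dict(channels=(32, 64, 128, 256)),
        dict(channels=(32, 32, 128, 256, 512)),
        dict(heads=(3, 4, 8, 8, 16)),
        dict(input_size=100),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelConfig(**{**TINY, **bad})

    def test_json_round_trip(self):
        cfg = ModelConfig(**TINY)
        assert ModelConfig.from_json(cfg.to_json()) == cfg


class TestDwsConv:
    def test_parameter_count_closed_form(self):
        conv = DepthwiseSeparableConv(np.random.default_rng(0), 3, 8, kernel=3)
        # depthwise C*k^2 + bias C; pointwise C*C_out + bias; norm 2*C_out
        expect = 3 * 9 + 3 + 3 * 8 + 8 + 2 * 8
        assert count_parameters(conv) == expect

    def test_cheaper_than_full_conv(self):
        c_in, c_out, k = 16, 32, 3
        dws = c_in * k * k + c_in * c_out
        assert dws < c_in * c_out * k * k

    def test_identity_kernels_reduce_to_activated_norm(self, rng):
        conv = DepthwiseSeparableConv(np.random.default_rng(1), 4, 4, kernel=3)
        conv.depthwise.weight.data[:] = 0
        conv.depthwise.weight.data[1, 1, :] = 1.0     # centre tap
        conv.depthwise.bias.data[:] = 0
        conv.pointwise.weight.data = np.eye(4, dtype=np.float32)
        conv.pointwise.bias.data[:] = 0
        x = rng.normal(size=(1, 5, 5, 4)).astype(np.float32)
        expect = conv.norm(Tensor(x)).silu().numpy()
        assert np.allclose(conv(Tensor(x)).numpy(), expect, atol=1e-6)

    def test_shape_contract(self, rng):
        conv = DepthwiseSeparableConv(np.random.default_rng(2), 3, 7)
        x = rng.normal(size=(2, 6, 9, 3)).astype(np.float32)
        assert conv(Tensor(x)).shape == (2, 6, 9, 7)


class TestDownsample:
    def test_constant_preserved_then_projected(self, rng):
        ds = Downsample(np.random.default_rng(0), 3, 5)
        x = np.full((1, 8, 8, 3), 2.0, np.float32)
        out = ds(Tensor(x)).numpy()
        expect = np.full((1, 4, 4, 3), 2.0, np.float32) @ ds.proj.weight.data \
            + ds.proj.bias.data
        assert np.allclose(out, expect, atol=1e-6)

    def test_two_halvings_quarter_resolution(self, rng):
        d1 = Downsample(np.random.default_rng(1), 3, 4)
        d2 = Downsample(np.random.default_rng(2), 4, 5)
        x = Tensor(rng.normal(size=(1, 16, 16, 3)).astype(np.float32))
        assert d2(d1(x)).shape == (1, 4, 4, 5)

    def test_one_pixel_extent_rejected(self):
        ds = Downsample(np.random.default_rng(0), 3, 4)
        with pytest.raises(ValueError):
            ds(Tensor(np.zeros((1, 1, 4, 3), np.float32)))


class TestEncodeDecode:
    def test_stage_resolutions_and_channels(self):
        model = SegModel(ModelConfig(**SMOKE_CONFIG), seed=0)
        x = Tensor(np.zeros((1, 64, 64, 3), np.float32))
        with no_grad():
            bundles = model.encode(x)
        sizes = [b.fused.shape[1] for b in bundles]
        chans = [b.fused.shape[3] for b in bundles]
        assert sizes == [32, 16, 8, 4, 2]
        assert chans == list(model.cfg.channels)
        for b in bundles:
            assert b.e_t.shape == b.e_m.shape == b.e_d.shape == b.fused.shape

    def test_zero_weights_still_finite(self):
        model = tiny_model()
        zero_all_parameters(model)
        with no_grad():
            out = model(Tensor(np.random.default_rng(0)
                               .normal(size=(1, 32, 32, 3)).astype(np.float32)))
        assert np.isfinite(out.numpy()).all()

    def test_logits_match_input_size_and_are_finite(self, rng):
        model = tiny_model()
        for seed in range(3):
            x = np.random.default_rng(seed).normal(size=(2, 32, 32, 3))
            with no_grad():
                out = model(Tensor(x.astype(np.float32)))
            assert out.shape == (2, 32, 32, 1)
            assert np.isfinite(out.numpy()).all()

    def test_indivisible_input_rejected(self):
        model = tiny_model()
        with pytest.raises(ValueError):
            model(Tensor(np.zeros((1, 33, 32, 3), np.float32)))

    def test_gradient_reaches_every_component_group(self, rng):
        model = tiny_model()
        x = Tensor(rng.normal(size=(1, 32, 32, 3)).astype(np.float32))
        loss = (model(x).sigmoid() ** 2).mean()
        loss.backward()
        grads = {name: p.grad for name, p in model.named_parameters()}
        for group in ("cst.", "vme.", "dws.", "mtm.", "dec.", "head"):
            group_grads = [g for n, g in grads.items() if n.startswith(group)]
            assert group_grads, group
            assert any(g is not None and np.any(g != 0) for g in group_grads), group

    def test_fixed_seed_reproduces_logits(self, rng):
        x = rng.normal(size=(1, 32, 32, 3)).astype(np.float32)
        with no_grad():
            a = tiny_model(seed=5)(Tensor(x)).numpy()
            b = tiny_model(seed=5)(Tensor(x)).numpy()
        assert np.array_equal(a, b)


class TestProfile:
    def test_param_count_matches_enumeration(self):
        cfg = ModelConfig(**TINY)
        rep = profile(cfg)
        assert rep.params == count_parameters(SegModel(cfg, seed=0))
        assert rep.macs > 0
        assert np.isclose(rep.flops_g, 2 * rep.flops_mac1_g, atol=0.1)

    def test_macs_grow_with_input_area(self):
        cfg64 = ModelConfig(**SMOKE_CONFIG)
        r64 = profile(cfg64)
        r128 = profile(cfg64, input_size=128)
        assert r128.macs > 3 * r64.macs      # conv terms scale 4x, attention faster
        assert r128.params > r64.params      # positional tables grow


class TestCheckpoint:
    def test_round_trip_preserves_weights_and_config(self, tmp_path, rng):
        model = tiny_model(seed=3)
        p = tmp_path / "ck.npz"
        save_checkpoint(p, model, seed=3, iteration=17)
        loaded, meta = load_checkpoint(p)
        assert meta["iteration"] == 17
        assert loaded.cfg == model.cfg
        x = Tensor(rng.normal(size=(1, 32, 32, 3)).astype(np.float32))
        with no_grad():
            assert np.array_equal(model(x).numpy(), loaded(x).numpy())

    def test_rejects_foreign_files(self, tmp_path):
        p = tmp_path / "junk.npz"
        np.savez(p, a=np.zeros(3))
        with pytest.raises(Exception):
            load_checkpoint(p)
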