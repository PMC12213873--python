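"""Five-stage dual-encoder segmentation backbone.

Topology: at each pyramid stage i (spatial size input/2^i, channels C_i)
three parallel streams each consume their own previous-stage output
through a bilinear half-resolution downsample plus pointwise channel
projection:

* a Cross Shape Transformer stack (E_T),
* a Vision-Mamba stack (E_M),
* a depthwise-separable convolution auxiliary layer (E_D).

E_T and E_M are fused per stage by the MTM module; the decoder then
walks deepest-to-shallowest, each level concatenating the fused map,
the upsampled previous decoder output and the auxiliary map through two
3x3 conv + norm + SiLU layers, ending in a 1x1 head and a bilinear
upsample to the input size. The head emits logits; apply a sigmoid for
probabilities (binary task, one output channel by default; a 3-channel
head is available via ``out_channels``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .tensor import Tensor, concat, mac_counter, no_grad, resize_bilinear
from .nn import (Conv2d, DepthwiseSeparableConv, LayerNorm, Linear, Module,
                 ModuleList, count_parameters)
from .csa import CSTBlock
from .mtm import MTMFusion
from .vim import VmeStage

__all__ = ["ModelConfig", "StageBundle", "Downsample", "DecoderBlock",
           "SegModel", "build_model", "profile", "ProfileReport",
           "save_checkpoint", "load_checkpoint", "SMOKE_CONFIG", "default_config"]

N_STAGES = 5


@dataclass
class ModelConfig:
    """Architecture hyperparameters (5 pyramid stages).

    The shipped defaults are the calibrated configuration recorded in
    the config reference (docs/methods.md): channel schedule
    (32, 64, 128, 256, 512), strip width 3, and the per-stage depth
    schedule that lands the 256x256 parameter/FLOP budget.
    """

    channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    depths_cst: tuple[int, ...] = (50, 3, 4, 4, 11)
    depths_vme: tuple[int, ...] = (50, 3, 4, 4, 11)
    heads: tuple[int, ...] = (2, 4, 8, 8, 16)
    sw: int | tuple[int, ...] = 3
    mlp_ratio: float | tuple[float, ...] = 4.0
    d_state: int = 16
    expand: int = 2
    conv_kernel: int = 4
    input_size: int = 256
    out_channels: int = 1
    mtm_gate: bool = True

    def __post_init__(self):
        for name in ("channels", "depths_cst", "depths_vme", "heads"):
            val = tuple(getattr(self, name))
            object.__setattr__(self, name, val)
            if len(val) != N_STAGES:
                raise ValueError(f"{name} must list {N_STAGES} stages, got {len(val)}")
        if any(b <= a for a, b in zip(self.channels, self.channels[1:])):
            raise ValueError("channels must be strictly increasing")
        for k, c in zip(self.heads, self.channels):
            if k % 2 or c % k:
                raise ValueError(f"head count {k} must be even and divide {c}")
        if self.input_size % 2 ** N_STAGES:
            raise ValueError(f"input_size must be divisible by {2 ** N_STAGES}")

    def sw_at(self, i: int) -> int:
        return self.sw[i] if isinstance(self.sw, (tuple, list)) else self.sw

    def ratio_at(self, i: int) -> float:
        r = self.mlp_ratio
        return r[i] if isinstance(r, (tuple, list)) else r

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        for key in ("channels", "depths_cst", "depths_vme", "heads"):
            d[key] = tuple(d[key])
        for key in ("sw", "mlp_ratio"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)


def default_config() -> ModelConfig:
    """The calibrated default (see the config reference in docs/methods.md)."""
    return ModelConfig()


#: width-reduced configuration for desk-scale smoke training
SMOKE_CONFIG = dict(channels=(8, 16, 32, 64, 128), depths_cst=(1,) * 5,
                    depths_vme=(1,) * 5, heads=(2, 2, 2, 2, 2), input_size=64,
                    d_state=8)


@dataclass
class StageBundle:
    """The four per-stage outputs at one pyramid level."""

    e_t: Tensor
    e_m: Tensor
    e_d: Tensor
    fused: Tensor

    def __post_init__(self):
        shapes = {t.shape for t in (self.e_t, self.e_m, self.e_d, self.fused)}
        if len(shapes) != 1:
            raise ValueError(f"stage outputs disagree in shape: {shapes}")


class Downsample(Module):
    """Bilinear half-resolution + pointwise projection to the next width."""

    def __init__(self, rng, in_ch: int, out_ch: int):
        self.proj = Linear(rng, in_ch, out_ch)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        if H < 2 or W < 2:
            raise ValueError("cannot halve a 1-pixel extent")
        y = resize_bilinear(x, (H + 1) // 2, (W + 1) // 2)
        return self.proj(y)


class CSTStage(Module):
    def __init__(self, rng, dim, depth, heads, sw, mlp_ratio):
        self.blocks = ModuleList(
            CSTBlock(rng, dim, heads, sw, mlp_ratio) for _ in range(depth))

    def forward(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk(x)
        return x


class DecoderBlock(Module):
    """Two 3x3 conv + norm + SiLU layers."""

    def __init__(self, rng, in_ch: int, out_ch: int):
        self.conv1 = Conv2d(rng, in_ch, out_ch, 3)
        self.norm1 = LayerNorm(out_ch)
        self.conv2 = Conv2d(rng, out_ch, out_ch, 3)
        self.norm2 = LayerNorm(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(self.conv1(x)).silu()
        return self.norm2(self.conv2(x)).silu()


class SegModel(Module):
    """The assembled dual-encoder U-shaped segmentation network."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        chans = (3,) + cfg.channels
        size = cfg.input_size
        self.down_t = ModuleList(Downsample(rng, chans[i], chans[i + 1])
                                 for i in range(N_STAGES))
        self.down_m = ModuleList(Downsample(rng, chans[i], chans[i + 1])
                                 for i in range(N_STAGES))
        self.down_d = ModuleList(Downsample(rng, chans[i], chans[i + 1])
                                 for i in range(N_STAGES))
        self.cst = ModuleList(
            CSTStage(rng, cfg.channels[i], cfg.depths_cst[i], cfg.heads[i],
                     cfg.sw_at(i), cfg.ratio_at(i)) for i in range(N_STAGES))
        self.vme = ModuleList(
            VmeStage(rng, cfg.channels[i], cfg.depths_vme[i],
                     grid_shape=(size // 2 ** (i + 1), size // 2 ** (i + 1)),
                     d_state=cfg.d_state, expand=cfg.expand,
                     conv_kernel=cfg.conv_kernel) for i in range(N_STAGES))
        self.dws = ModuleList(
            DepthwiseSeparableConv(rng, cfg.channels[i], cfg.channels[i])
            for i in range(N_STAGES))
        self.mtm = ModuleList(
            MTMFusion(rng, cfg.channels[i], gate_enabled=cfg.mtm_gate)
            for i in range(N_STAGES))
        self.up_proj = ModuleList(
            Linear(rng, cfg.channels[i + 1], cfg.channels[i])
            for i in range(N_STAGES - 1))
        self.dec = ModuleList(
            DecoderBlock(rng,
                         (2 if i == N_STAGES - 1 else 3) * cfg.channels[i],
                         cfg.channels[i])
            for i in range(N_STAGES))
        self.head = Linear(rng, cfg.channels[0], cfg.out_channels)

    # ---- encoder -------------------------------------------------------
    def encode(self, image: Tensor) -> list[StageBundle]:
        B, H, W, C = image.shape
        if H % 2 ** N_STAGES or W % 2 ** N_STAGES:
            raise ValueError(f"input extent must be divisible by {2 ** N_STAGES}")
        bundles = []
        x_t = x_m = x_d = image
        for i in range(N_STAGES):
            e_t = self.cst[i](self.down_t[i](x_t))
            e_m = self.vme[i](self.down_m[i](x_m))
            e_d = self.dws[i](self.down_d[i](x_d))
            bundles.append(StageBundle(e_t, e_m, e_d, self.mtm[i](e_t, e_m)))
            x_t, x_m, x_d = e_t, e_m, e_d
        return bundles

    # ---- decoder -------------------------------------------------------
    def decode(self, bundles: list[StageBundle], out_size: tuple[int, int]) -> Tensor:
        d = None
        for i in range(N_STAGES - 1, -1, -1):
            b = bundles[i]
            if d is None:
                x = concat([b.fused, b.e_d], axis=-1)
            else:
                h, w = b.fused.shape[1:3]
                up = self.up_proj[i](resize_bilinear(d, h, w))
                x = concat([b.fused, up, b.e_d], axis=-1)
            d = self.dec[i](x)
        logits = self.head(d)
        return resize_bilinear(logits, *out_size)

    def forward(self, image: Tensor) -> Tensor:
        """Image (B, H, W, 3) -> logits (B, H, W, out_channels)."""
        if not isinstance(image, Tensor):
            image = Tensor(np.asarray(image, dtype=np.float32))
        return self.decode(self.encode(image), image.shape[1:3])


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> SegModel:
    return SegModel(cfg or default_config(), seed=seed)


# ---------------------------------------------------------------------------
# profiling
# ---------------------------------------------------------------------------

@dataclass
class ProfileReport:
    """Parameter and forward-cost budget of a configuration.

    ``macs`` counts multiply-accumulates of the dense linear-algebra ops
    (matmuls of projections/attention, convolutions, interpolation and
    the SSM recurrence) over one forward pass. ``flops`` reports the
    2-FLOPs-per-MAC convention; ``flops_mac1`` the 1-FLOP-per-MAC one.
    """

    params: int
    macs: int
    input_size: int

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    @property
    def flops_g(self) -> float:
        return 2 * self.macs / 1e9

    @property
    def flops_mac1_g(self) -> float:
        return self.macs / 1e9

    def as_dict(self) -> dict:
        return {"input_size": self.input_size, "params": self.params,
                "params_M": round(self.params_m, 1), "macs": self.macs,
                "flops_G_2macs": round(self.flops_g, 1),
                "flops_G_1mac": round(self.flops_mac1_g, 1)}

    def __str__(self) -> str:
        return (f"input {self.input_size}x{self.input_size}: "
                f"{self.params_m:.1f} M params, {self.macs / 1e9:.1f} GMACs "
                f"({self.flops_g:.1f} GFLOPs at 2 FLOPs/MAC)")


def profile(cfg: ModelConfig | None = None, input_size: int | None = None,
            seed: int = 0) -> ProfileReport:
    """Instantiate a configuration and measure its budget.

    Parameters are enumerated from the instantiated model; MACs are
    accumulated by the tape while running one forward pass on a single
    ``input_size`` x ``input_size`` x 3 input.
    """
    cfg = cfg or default_config()
    if input_size is not None and input_size != cfg.input_size:
        d = asdict(cfg)
        d["input_size"] = input_size
        for key in ("channels", "depths_cst", "depths_vme", "heads"):
            d[key] = tuple(d[key])
        cfg = ModelConfig(**d)
    model = SegModel(cfg, seed=seed)
    n_params = count_parameters(model)
    x = np.zeros((1, cfg.input_size, cfg.input_size, 3), dtype=np.float32)
    with no_grad(), mac_counter() as cell:
        model(Tensor(x))
    return ProfileReport(params=n_params, macs=cell[0], input_size=cfg.input_size)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: SegModel, seed: int = 0, iteration: int = 0,
                    extra: dict | None = None) -> None:
    """Self-describing container: config + weights + seed + iteration."""
    meta = {"config": asdict(model.cfg), "seed": seed, "iteration": iteration,
            "format": "stripmamba-checkpoint-v1", "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[SegModel, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("format") != "stripmamba-checkpoint-v1":
            raise ValueError(f"not a recognised checkpoint: {path}")
        cfg = ModelConfig.from_json(json.dumps(meta["config"]))
        model = SegModel(cfg, seed=meta.get("seed", 0))
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model, meta
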