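"""Training loop, optimiser, prediction and evaluation.

The recipe mirrors standard practice for this architecture family:
Adam, base learning rate 1e-4 with a polynomial decay
lr(t) = lr0 * (1 - t/T)^0.9, combined BCE + Dice loss with unit
weights, 5000 iterations at batch size 8, inputs resized to 384x384
and standardised per channel. All of these are configuration fields;
the desk-scale smoke settings used by the tests shrink the model and
the schedule but change no mechanism.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from . import __version__
from .tensor import Tensor, no_grad
from .data import AugmentConfig, augment, load_dataset, standardize
from .losses import LossWeights, aggregate_metrics, seg_metrics, total_loss
from .model import ModelConfig, SegModel, load_checkpoint, save_checkpoint
from .synth import SegSample

__all__ = ["TrainConfig", "Adam", "poly_lr", "train", "predict", "evaluate"]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    poly_power: float = 0.9
    max_iters: int = 5000
    batch_size: int = 8
    resize: int = 384
    seed: int = 0
    loss: LossWeights = field(default_factory=LossWeights)
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    keep_best_by_train_dice: bool = False
    log_every: int = 50

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.resize % 32:
            raise ValueError("resize must be divisible by 32")


def poly_lr(base_lr: float, iteration: int, max_iters: int, power: float = 0.9) -> float:
    """lr(t) = lr0 * (1 - t/T)^power; equals lr0 at t=0 and 0 at t=T."""
    return base_lr * (1.0 - iteration / max_iters) ** power


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _prep(sample: SegSample, size: int) -> tuple[np.ndarray, np.ndarray]:
    img, mask = sample.image, sample.mask
    if img.shape[:2] != (size, size):
        img = _sk_resize(img, (size, size), order=1, preserve_range=True,
                         anti_aliasing=False).astype(np.float32)
        mask = _sk_resize(mask.astype(float), (size, size), order=0,
                          preserve_range=True, anti_aliasing=False)
        mask = (mask > 0.5).astype(np.uint8)
    return standardize(img).astype(np.float32), mask.astype(np.float32)


def _make_batch(samples, idx, size, rng, aug_cfg):
    imgs, masks = [], []
    for i in idx:
        s = samples[i]
        if aug_cfg is not None:
            s = augment(s, rng, aug_cfg)
        im, m = _prep(s, size)
        imgs.append(im)
        masks.append(m)
    return np.stack(imgs), np.stack(masks)[..., None]


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, data, out_dir=None,
          model: SegModel | None = None):
    """Train a model; ``data`` is a dataset root or a list of samples.

    Returns ``(model, history)`` where history is a list of per-logged-
    iteration records. A NaN loss aborts with a diagnostic. With
    ``out_dir`` set, a config/seed/version log, the loss history and a
    final checkpoint (plus optionally the best-by-train-Dice one) are
    written there.
    """
    if model_cfg.input_size != train_cfg.resize:
        raise ValueError(
            f"model input_size {model_cfg.input_size} != training resize "
            f"{train_cfg.resize}; positional tables are built per resolution")
    samples = load_dataset(data) if not isinstance(data, list) else data
    if not samples:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(train_cfg.seed)
    if model is None:
        model = SegModel(model_cfg, seed=train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.lr)
    history = []
    t0 = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "train_log.json").write_text(json.dumps({
            "version": __version__, "seed": train_cfg.seed,
            "model_config": asdict(model_cfg),
            "train_config": _cfg_dict(train_cfg)}, indent=2, default=str))
    best_dice, best_state = -1.0, None
    for it in range(train_cfg.max_iters):
        idx = rng.integers(0, len(samples), size=train_cfg.batch_size)
        x, g = _make_batch(samples, idx, train_cfg.resize, rng, train_cfg.augment)
        logits = model(Tensor(x))
        loss = total_loss(logits, Tensor(g), train_cfg.loss, from_logits=True)
        lval = loss.item()
        if not math.isfinite(lval):
            raise RuntimeError(
                f"loss diverged (non-finite) at iteration {it}; "
                f"lr={opt.lr:.2e}, batch indices={idx.tolist()}")
        opt.zero_grad()
        loss.backward()
        opt.lr = poly_lr(train_cfg.lr, it + 1, train_cfg.max_iters,
                         train_cfg.poly_power)
        opt.step()
        rec = {"iter": it, "loss": lval, "lr": opt.lr}
        if it == 0 or (it + 1) % train_cfg.log_every == 0 or it == train_cfg.max_iters - 1:
            history.append(rec)
        if train_cfg.keep_best_by_train_dice and (it + 1) % train_cfg.log_every == 0:
            d = _train_dice(model, samples, train_cfg)
            rec["train_dice"] = d
            if d > best_dice:
                best_dice, best_state = d, model.state_dict()
    wall = time.time() - t0
    if out is not None:
        save_checkpoint(out / "checkpoint.npz", model, seed=train_cfg.seed,
                        iteration=train_cfg.max_iters, extra={"wall_time_s": wall})
        if best_state is not None:
            model_best = SegModel(model_cfg, seed=train_cfg.seed)
            model_best.load_state_dict(best_state)
            save_checkpoint(out / "checkpoint_best.npz", model_best,
                            seed=train_cfg.seed, iteration=train_cfg.max_iters,
                            extra={"train_dice": best_dice})
        (out / "history.json").write_text(json.dumps(
            {"history": history, "wall_time_s": wall}, indent=2))
    return model, history


def _cfg_dict(tc: TrainConfig) -> dict:
    d = asdict(tc)
    return d


def _train_dice(model, samples, train_cfg, threshold: float = 0.5) -> float:
    reports = []
    with no_grad():
        for s in samples:
            im, m = _prep(s, train_cfg.resize)
            logits = model(Tensor(im[None]))
            pred = _sigmoid_np(logits.numpy()[0, :, :, 0]) >= threshold
            reports.append(seg_metrics(pred, m > 0.5))
    return aggregate_metrics(reports)["dice"]


def _sigmoid_np(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def predict(checkpoint, images, out_dir, threshold: float = 0.5) -> list[Path]:
    """Write per-image probability maps and binarised masks as PNG.

    ``images`` is a directory of PNG/JPEG files or a list of paths.
    Output masks match each input image's size.
    """
    model, _meta = (checkpoint if isinstance(checkpoint, tuple)
                    else load_checkpoint(checkpoint))
    size = model.cfg.input_size
    if isinstance(images, (str, Path)) and Path(images).is_dir():
        paths = sorted(p for p in Path(images).iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    else:
        paths = [Path(p) for p in images]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for p in paths:
        img = np.asarray(Image.open(p).convert("RGB"), dtype=np.float32) / 255.0
        H, W = img.shape[:2]
        s = SegSample(image=img, mask=np.zeros((H, W), np.uint8),
                      provenance={"path": str(p)})
        im, _ = _prep(s, size)
        with no_grad():
            logits = model(Tensor(im[None]))
        prob = _sigmoid_np(logits.numpy()[0, :, :, 0])
        if prob.shape != (H, W):
            prob = _sk_resize(prob, (H, W), order=1, preserve_range=True)
        prob_path = out / f"{p.stem}_prob.png"
        mask_path = out / f"{p.stem}_mask.png"
        Image.fromarray((prob * 255).round().astype(np.uint8)).save(prob_path)
        Image.fromarray(((prob >= threshold) * 255).astype(np.uint8)).save(mask_path)
        written += [prob_path, mask_path]
    return written


def evaluate(checkpoint, data_root, threshold: float = 0.5,
             report_path=None) -> dict:
    """Run the metrics over a dataset; returns per-image records plus the
    dataset aggregate, optionally written as JSON."""
    model, _meta = (checkpoint if isinstance(checkpoint, tuple)
                    else load_checkpoint(checkpoint))
    samples = load_dataset(data_root) if not isinstance(data_root, list) else data_root
    size = model.cfg.input_size
    records, reports = [], []
    for s in samples:
        im, m = _prep(s, size)
        with no_grad():
            logits = model(Tensor(im[None]))
        pred = _sigmoid_np(logits.numpy()[0, :, :, 0]) >= threshold
        rep = seg_metrics(pred, m > 0.5)
        reports.append(rep)
        records.append(dict(stem=s.provenance.get("stem",
                                                  str(s.provenance.get("seed", ""))),
                            **rep.as_dict()))
    result = {"per_image": records, "aggregate": aggregate_metrics(reports),
              "threshold": threshold, "n": len(reports)}
    if report_path is not None:
        Path(report_path).write_text(json.dumps(result, indent=2))
    return result
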