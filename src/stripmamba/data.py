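"""Dataset reading and training-time augmentation.

The on-disk layout is Kvasir-SEG-compatible: ``images/`` and ``masks/``
with matching stems; masks are binarised at 127/255 when read. The
augmentation pipeline applies, in order: random horizontal/vertical
flips (joint), photometric distortion (image only), reflect padding to
the target extent (mask zero-padded), and a random affine warp with
nearest-neighbour mask resampling — so the mask stays strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .synth import SegSample

__all__ = ["AugmentConfig", "load_dataset", "augment", "standardize"]


@dataclass(frozen=True)
class AugmentConfig:
    """Flags and magnitudes; all-off makes :func:`augment` the identity."""

    flip: bool = True
    photometric: bool = True
    warp: bool = True
    pad_to: int | None = None
    brightness: float = 0.2          # additive, +/-
    contrast: tuple[float, float] = (0.8, 1.25)
    saturation: tuple[float, float] = (0.8, 1.25)
    max_rotation_deg: float = 10.0
    scale: tuple[float, float] = (0.9, 1.1)
    max_shear_deg: float = 5.0


def load_dataset(root) -> list[SegSample]:
    """Read image/mask pairs with matching stems, stem-sorted.

    Images are scaled to [0, 1]; masks binarised at 127/255. Orphan
    stems on either side raise with the offending names listed.
    """
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"expected {img_dir} and {mask_dir}")
    imgs = {p.stem: p for p in img_dir.iterdir() if p.suffix.lower() in
            (".png", ".jpg", ".jpeg")}
    masks = {p.stem: p for p in mask_dir.iterdir() if p.suffix.lower() in
             (".png", ".jpg", ".jpeg")}
    orphans = sorted(set(imgs) ^ set(masks))
    if orphans:
        raise ValueError(f"unmatched stems between images/ and masks/: {orphans}")
    samples = []
    for stem in sorted(imgs):
        try:
            img = np.asarray(Image.open(imgs[stem]).convert("RGB"),
                             dtype=np.float32) / 255.0
            m = np.asarray(Image.open(masks[stem]).convert("L"))
        except OSError as e:
            raise OSError(f"unreadable file for stem {stem!r}: {e}") from e
        samples.append(SegSample(image=img, mask=(m > 127).astype(np.uint8),
                                 provenance={"path": str(imgs[stem]), "stem": stem}))
    return samples


def standardize(image: np.ndarray) -> np.ndarray:
    """Per-channel zero-mean unit-variance normalisation of one image."""
    mu = image.mean(axis=(0, 1), keepdims=True)
    sd = image.std(axis=(0, 1), keepdims=True)
    return (image - mu) / np.maximum(sd, 1e-6)


def _affine_params(rng: np.random.Generator, cfg: AugmentConfig):
    rot = np.deg2rad(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    scale = rng.uniform(*cfg.scale)
    shear = np.deg2rad(rng.uniform(-cfg.max_shear_deg, cfg.max_shear_deg))
    c, s = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s], [s, c]])
    Sh = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    return (R @ Sh) * scale


def augment(sample: SegSample, rng: np.random.Generator,
            cfg: AugmentConfig = AugmentConfig()) -> SegSample:
    """Random joint augmentation of one sample; see the module docstring
    for the order of operations."""
    img = sample.image.copy()
    mask = sample.mask.copy()

    if cfg.flip:
        if rng.random() < 0.5:
            img, mask = img[:, ::-1], mask[:, ::-1]
        if rng.random() < 0.5:
            img, mask = img[::-1], mask[::-1]

    if cfg.photometric:
        img = img + rng.uniform(-cfg.brightness, cfg.brightness)
        img = (img - img.mean()) * rng.uniform(*cfg.contrast) + img.mean()
        gray = img.mean(axis=-1, keepdims=True)
        img = gray + (img - gray) * rng.uniform(*cfg.saturation)
        img = np.clip(img, 0.0, 1.0)

    if cfg.pad_to is not None:
        H, W = mask.shape
        ph, pw = max(cfg.pad_to - H, 0), max(cfg.pad_to - W, 0)
        if ph or pw:
            pads = ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2))
            img = np.pad(img, pads + ((0, 0),), mode="reflect")
            mask = np.pad(mask, pads, mode="constant")

    if cfg.warp:
        M = _affine_params(rng, cfg)
        H, W = mask.shape
        centre = np.array([(H - 1) / 2, (W - 1) / 2])
        offset = centre - M @ centre
        img = np.stack([ndimage.affine_transform(
            img[..., c], M, offset=offset, order=1, mode="reflect")
            for c in range(img.shape[-1])], axis=-1)
        mask = ndimage.affine_transform(mask, M, offset=offset, order=0,
                                        mode="constant", cval=0)
        img = np.clip(img, 0.0, 1.0)

    return SegSample(image=np.ascontiguousarray(img, dtype=np.float32),
                     mask=np.ascontiguousarray(mask).astype(np.uint8),
                     provenance=dict(sample.provenance, augmented=True))
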