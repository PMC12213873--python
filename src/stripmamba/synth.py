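"""Seeded generator of polyp-like image/mask pairs.

Emulates the qualitative difficulty of endoscopic polyp imagery —
lesions of varying size, blurred boundaries, and weak contrast against
the background — as smooth random blobs on textured, endoscopy-tinted
backgrounds. Masks are rasterised *before* any image-domain blurring:
the ground truth stays crisp while the image boundary is ambiguous,
which preserves rather than trivialises the segmentation challenge.

Generation is a pure function of (config, seed): the same pair is
bit-identical across calls, platforms permitting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["SynthConfig", "SegSample", "gen_blob_mask", "gen_sample", "gen_dataset"]

# endoscopy-like palette: warm mucosal pink, lesion slightly redder
_BG_TINT = np.array([0.62, 0.35, 0.32])
# radius-2 disk structuring element for morphological closing
_YX = np.mgrid[-2:3, -2:3]
_DISK2 = (_YX[0] ** 2 + _YX[1] ** 2) <= 4
_LESION_TINT = np.array([1.0, 0.55, 0.5])


@dataclass(frozen=True)
class SynthConfig:
    """Generator controls.

    ``contrast`` is the mean intensity offset of lesion vs background
    (0 = invisible); ``boundary_blur_sigma`` is the Gaussian width in
    pixels applied to the lesion's image contribution (not the mask);
    ``background_texture_scale`` is the correlation length in pixels of
    the background texture.
    """

    image_size: int = 256
    n_polyps_range: tuple[int, int] = (1, 2)
    area_fraction_range: tuple[float, float] = (0.03, 0.20)
    contrast: float = 0.25
    boundary_blur_sigma: float = 2.0
    background_texture_scale: float = 12.0
    texture_amplitude: float = 0.08
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.area_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("area_fraction_range must lie inside (0, 1)")
        if self.boundary_blur_sigma < 0:
            raise ValueError("boundary_blur_sigma must be >= 0")

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True)
                              .encode()).hexdigest()[:12]


@dataclass
class SegSample:
    """Paired image + binary mask with provenance."""

    image: np.ndarray          # (H, W, 3) float in [0, 1]
    mask: np.ndarray           # (H, W) uint8 in {0, 1}
    provenance: dict

    def __post_init__(self):
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask must be strictly binary")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("image must be finite")


def gen_blob_mask(rng: np.random.Generator, size: int, area_fraction: float) -> np.ndarray:
    """One connected smooth region: an ellipse whose radius is modulated
    by a low-order random Fourier series, rasterised and morphologically
    closed. Returns a (size, size) uint8 mask in {0, 1}."""
    if area_fraction <= 0:
        return np.zeros((size, size), dtype=np.uint8)
    r0 = np.sqrt(area_fraction * size * size / np.pi)
    ecc = rng.uniform(0.7, 1.3)          # axis ratio of the base ellipse
    theta0 = rng.uniform(0, 2 * np.pi)
    n_harm = rng.integers(3, 7)
    amps = rng.uniform(0, 0.25 / n_harm, size=n_harm)
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)
    margin = min(1.35 * r0 * max(ecc, 1 / ecc), size / 2 - 1)
    cy = rng.uniform(margin, size - margin) if size > 2 * margin else size / 2
    cx = rng.uniform(margin, size - margin) if size > 2 * margin else size / 2

    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame
    ry = np.cos(theta0) * dy + np.sin(theta0) * dx
    rx = -np.sin(theta0) * dy + np.cos(theta0) * dx
    dist = np.sqrt((ry * ecc) ** 2 + (rx / ecc) ** 2)
    ang = np.arctan2(ry, rx)
    radius = r0 * (1.0 + sum(a * np.cos((k + 1) * ang + p)
                             for k, (a, p) in enumerate(zip(amps, phases))))
    mask = dist <= radius
    mask = ndimage.binary_closing(mask, structure=_DISK2)
    # keep only the largest connected component (star-convexity can be
    # broken at the image border)
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask.astype(np.uint8)


def _background(rng: np.random.Generator, size: int, scale: float,
                amplitude: float) -> np.ndarray:
    """Smoothed multi-octave noise tinted to the mucosal palette."""
    tex = np.zeros((size, size))
    for octave in range(3):
        s = max(scale / 2 ** octave, 0.75)
        layer = ndimage.gaussian_filter(rng.standard_normal((size, size)), s)
        std = layer.std()
        if std > 0:
            tex += layer / std / 2 ** octave
    tex *= amplitude / max(np.abs(tex).max(), 1e-9)
    # slight vignette, as in endoscope optics
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = ((yy - size / 2) ** 2 + (xx - size / 2) ** 2) / (size / 2) ** 2
    vignette = 1.0 - 0.25 * r2
    base = (0.85 + tex) * vignette
    return base[..., None] * _BG_TINT[None, None, :]


def gen_sample(cfg: SynthConfig, seed: int) -> SegSample:
    """Generate one image/mask pair, deterministic in (cfg, seed)."""
    rng = np.random.default_rng([cfg.seed, seed])
    size = cfg.image_size
    image = _background(rng, size, cfg.background_texture_scale,
                        cfg.texture_amplitude)
    mask = np.zeros((size, size), dtype=np.uint8)
    n_polyps = int(rng.integers(cfg.n_polyps_range[0], cfg.n_polyps_range[1] + 1))
    for _ in range(n_polyps):
        af = rng.uniform(*cfg.area_fraction_range)
        mask |= gen_blob_mask(rng, size, af)
    # image-domain lesion contribution: blurred boundary, crisp mask
    contrib = mask.astype(np.float64)
    if cfg.boundary_blur_sigma > 0:
        contrib = ndimage.gaussian_filter(contrib, cfg.boundary_blur_sigma)
    # mild interior texture so the lesion is not a flat disc
    bump = ndimage.gaussian_filter(rng.standard_normal((size, size)), 4.0)
    bstd = bump.std()
    if bstd > 0:
        bump = bump / bstd * 0.15
    shade = cfg.contrast * contrib * (1.0 + bump)
    image = image + shade[..., None] * _LESION_TINT[None, None, :]
    image = np.clip(image, 0.0, 1.0)
    return SegSample(image=image.astype(np.float32), mask=mask,
                     provenance={"seed": int(seed), "config": cfg.digest()})


def gen_dataset(cfg: SynthConfig, n: int, out_dir, overwrite: bool = False) -> Path:
    """Write ``n`` PNG pairs under ``out_dir`` in ``images/`` + ``masks/``
    (Kvasir-SEG-compatible layout) with a plain-text manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty (pass overwrite=True)")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    lines = [f"config_digest={cfg.digest()}"]
    lines += [f"{k}={v}" for k, v in asdict(cfg).items()]
    for i in range(n):
        s = gen_sample(cfg, i)
        Image.fromarray((s.image * 255).round().astype(np.uint8)).save(
            out / "images" / f"{i:05d}.png")
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(
            out / "masks" / f"{i:05d}.png")
        lines.append(f"sample_{i:05d}_seed={i}")
    (out / "manifest.txt").write_text("\n".join(lines) + "\n")
    return out
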