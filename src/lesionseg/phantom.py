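"""Synthetic ultrasound-like phantoms: speckled background + one dark lesion.

The lesion boundary is a star-convex polygon: an ellipse whose radius is
modulated per angle by smooth (low-order Fourier) noise scaled by the
``irregularity`` amplitude. The image is a background level darkened inside
the (softly blurred) lesion, multiplied by a speckle field built from the
squared magnitude of a smoothed complex Gaussian field (mean 1), then
Gaussian-blurred and clipped to [0, 1]. Every phantom is reproducible from
(spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .data import ImagePair, MASK_SUFFIX


@dataclass(frozen=True)
class PhantomSpec:
    size: int = 64
    radius_range: Tuple[float, float] = (0.12, 0.30)  # fraction of size
    irregularity: float = 0.25
    lesion_contrast: float = 0.65
    speckle_scale: float = 0.5
    blur_sigma: float = 0.8
    background_level: float = 0.55
    seed: int = 0

    def __post_init__(self):
        if self.size % 16 != 0:
            raise ValueError(f"size must be divisible by 16, got {self.size}")
        lo, hi = self.radius_range
        if not (0.0 < lo <= hi < 0.45):
            raise ValueError(f"radius_range must lie within (0, 0.45), got {self.radius_range}")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")
        if not (0.0 < self.lesion_contrast < 1.0):
            raise ValueError("lesion_contrast must lie in (0, 1)")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be >= 0")


def _radial_profile(rng: np.random.Generator, n_angles: int, irregularity: float,
                    n_harmonics: int = 5) -> np.ndarray:
    """Smooth multiplicative modulation 1 + irregularity * f(theta), |f| <= 1."""
    theta = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    f = np.zeros(n_angles)
    for k in range(2, 2 + n_harmonics):
        amp = rng.normal() / k
        phase = rng.uniform(0, 2 * np.pi)
        f += amp * np.cos(k * theta + phase)
    peak = np.abs(f).max()
    if peak > 1e-9:
        f = f / peak
    return 1.0 + irregularity * f


def lesion_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Binary mask of a single star-convex lesion."""
    s = spec.size
    lo, hi = spec.radius_range
    a = rng.uniform(lo, hi) * s
    b = rng.uniform(lo, hi) * s
    rot = rng.uniform(0, np.pi)
    margin = max(a, b) * (1 + spec.irregularity) + 2
    cy = rng.uniform(margin, s - margin) if s - margin > margin else s / 2
    cx = rng.uniform(margin, s - margin) if s - margin > margin else s / 2
    n_angles = 360
    theta = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    modulation = _radial_profile(rng, n_angles, spec.irregularity)
    # ellipse radius at each angle, then rotated
    r_ell = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    r = np.maximum(r_ell * modulation, 1.5)
    ys = cy + r * np.sin(theta + rot)
    xs = cx + r * np.cos(theta + rot)
    rr, cc = draw_polygon(ys, xs, shape=(s, s))
    mask = np.zeros((s, s), dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


def _speckle_field(shape: Tuple[int, int], rng: np.random.Generator,
                   scale: float, corr_sigma: float = 1.0) -> np.ndarray:
    """Multiplicative texture with mean 1: 1 + scale*(I/E[I] - 1)."""
    if scale == 0:
        return np.ones(shape)
    re = ndimage.gaussian_filter(rng.normal(size=shape), corr_sigma)
    im = ndimage.gaussian_filter(rng.normal(size=shape), corr_sigma)
    intensity = re**2 + im**2
    intensity /= intensity.mean()
    return np.clip(1.0 + scale * (intensity - 1.0), 0.0, None)


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator | None = None,
                     image_id: str = "phantom") -> ImagePair:
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mask = lesion_mask(spec, rng)
    soft = ndimage.gaussian_filter(mask.astype(np.float64), max(spec.blur_sigma, 0.5))
    base = spec.background_level * (1.0 - spec.lesion_contrast * soft)
    speckle = _speckle_field((spec.size, spec.size), rng, spec.speckle_scale)
    image = base * speckle
    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.blur_sigma)
    image = np.clip(image, 0.0, 1.0)
    return ImagePair(image=image, mask=mask, id=image_id)


def generate_dataset(n: int, spec: PhantomSpec, out_dir) -> List[dict]:
    """Write ``n`` phantom pairs as 8-bit PNGs plus a JSON manifest.

    Layout matches the loader convention: ``images/<id>.png`` and
    ``masks/<id>_mask.png``. Returns the manifest entries.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    msk_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    msk_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    manifest = []
    width = max(len(str(n - 1)), 3)
    for i in range(n):
        image_id = f"phantom_{i:0{width}d}"
        pair = generate_phantom(spec, rng, image_id=image_id)
        Image.fromarray(np.round(pair.image * 255).astype(np.uint8), "L").save(
            img_dir / f"{image_id}.png"
        )
        Image.fromarray((pair.mask * 255).astype(np.uint8), "L").save(
            msk_dir / f"{image_id}{MASK_SUFFIX}.png"
        )
        manifest.append({"id": image_id, "spec": asdict(spec), "index": i})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
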