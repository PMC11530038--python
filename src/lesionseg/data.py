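"""PNG folder datasets: loading, preprocessing, augmentation and splitting.

Layout convention: ``images/<id>.png`` paired with ``masks/<id><suffix>.png``
(default suffix ``_mask``). Images are converted to grayscale luminance in
[0, 1]; masks are binarized at 0.5 on load and stay binary through every
transform (masks are always resampled with nearest neighbour).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
from PIL import Image

MASK_SUFFIX = "_mask"


@dataclass(frozen=True)
class ImagePair:
    """One grayscale image with its aligned binary lesion mask."""

    image: np.ndarray  # (H, W) float in [0, 1] before normalization
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    id: str

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"{self.id}: image {self.image.shape} and mask {self.mask.shape} differ"
            )
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{self.id}: mask must be binary, got values {vals[:10]}")


def _read_gray(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            gray = im.convert("F") if im.mode in ("F", "I") else im.convert("L")
            arr = np.asarray(gray, dtype=np.float64)
    except OSError as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def load_pairs(image_dir, mask_dir, mask_suffix: str = MASK_SUFFIX) -> List[ImagePair]:
    """Load all matched image/mask pairs, sorted by id for determinism."""
    image_dir = Path(image_dir)
    mask_dir = Path(mask_dir)
    images = sorted(p for p in image_dir.glob("*.png"))
    unmatched = []
    pairs: List[ImagePair] = []
    for img_path in images:
        stem = img_path.stem
        mask_path = mask_dir / f"{stem}{mask_suffix}.png"
        if not mask_path.exists():
            unmatched.append(str(img_path.name))
            continue
        image = _read_gray(img_path)
        mask = (_read_gray(mask_path) >= 0.5).astype(np.uint8)
        pairs.append(ImagePair(image=image, mask=mask, id=stem))
    if unmatched:
        raise FileNotFoundError(
            f"no mask found (suffix {mask_suffix!r}) for images: {', '.join(unmatched)}"
        )
    return pairs


def _resize_array(arr: np.ndarray, size: int, resample) -> np.ndarray:
    im = Image.fromarray(arr.astype(np.float32), mode="F")
    return np.asarray(im.resize((size, size), resample=resample), dtype=np.float64)


def resize_pair(pair: ImagePair, size: int, image_interp: str = "bilinear") -> ImagePair:
    """Resize to ``size`` x ``size``; the mask always uses nearest neighbour."""
    if size % 16 != 0:
        raise ValueError(f"target size must be divisible by 16, got {size}")
    interp_map = {"bilinear": Image.BILINEAR, "nearest": Image.NEAREST}
    if image_interp not in interp_map:
        raise ValueError(f"unknown interpolation {image_interp!r}")
    if pair.image.shape == (size, size):
        return pair
    image = _resize_array(pair.image, size, interp_map[image_interp])
    mask = _resize_array(pair.mask.astype(np.float32), size, Image.NEAREST)
    return ImagePair(image=np.clip(image, 0.0, 1.0), mask=mask.astype(np.uint8), id=pair.id)


def augment(
    pair: ImagePair,
    rng: np.random.Generator,
    p_flip: float = 0.5,
    p_scale: float = 0.5,
    scale_range: Tuple[float, float] = (0.8, 1.25),
) -> ImagePair:
    """Random horizontal/vertical flips and isotropic rescale + crop/pad.

    Each flip axis is decided independently with probability ``p_flip``;
    the rescale is applied with probability ``p_scale``. Image and mask are
    transformed jointly so they stay aligned.
    """
    if not (0.0 <= p_flip <= 1.0):
        raise ValueError("p_flip must lie in [0, 1]")
    image, mask = pair.image, pair.mask
    if rng.random() < p_flip:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if rng.random() < p_flip:
        image, mask = image[::-1, :], mask[::-1, :]
    if p_scale > 0 and rng.random() < p_scale:
        factor = rng.uniform(*scale_range)
        image, mask = _rescale_crop(image, mask, factor)
    return ImagePair(image=np.ascontiguousarray(image),
                     mask=np.ascontiguousarray(mask), id=pair.id)


def _rescale_crop(image: np.ndarray, mask: np.ndarray, factor: float):
    h, w = image.shape
    nh, nw = max(int(round(h * factor)), 1), max(int(round(w * factor)), 1)
    im = np.asarray(
        Image.fromarray(image.astype(np.float32), "F").resize((nw, nh), Image.BILINEAR),
        dtype=np.float64,
    )
    mk = np.asarray(
        Image.fromarray(mask.astype(np.float32), "F").resize((nw, nh), Image.NEAREST),
        dtype=np.float64,
    ).astype(np.uint8)
    if nh >= h:  # center crop back
        top, left = (nh - h) // 2, (nw - w) // 2
        return im[top : top + h, left : left + w], mk[top : top + h, left : left + w]
    out_im = np.zeros((h, w), dtype=im.dtype)
    out_mk = np.zeros((h, w), dtype=np.uint8)
    top, left = (h - nh) // 2, (w - nw) // 2
    out_im[top : top + nh, left : left + nw] = im
    out_mk[top : top + nh, left : left + nw] = mk
    return out_im, out_mk


def normalize(pair: ImagePair, mean: float, std: float) -> ImagePair:
    """Standardize the image as (image - mean) / std; the mask is untouched."""
    if std <= 0:
        raise ValueError(f"std must be > 0, got {std}")
    return replace(pair, image=(pair.image - mean) / std)


def dataset_statistics(pairs: Sequence[ImagePair]) -> Tuple[float, float]:
    """Pooled pixel mean and standard deviation over a set of pairs."""
    pixels = np.concatenate([p.image.ravel() for p in pairs])
    return float(pixels.mean()), float(pixels.std())


def split_dataset(
    pairs: Sequence[ImagePair], train_frac: float = 0.8, seed: int = 0
) -> Tuple[List[ImagePair], List[ImagePair]]:
    """Seeded shuffle into disjoint train/test; |train| = round(train_frac*n)."""
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 pairs to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(train_frac * n + 0.5))
    train_idx = sorted(order[:n_train].tolist())
    test_idx = sorted(order[n_train:].tolist())
    return [pairs[i] for i in train_idx], [pairs[i] for i in test_idx]


def write_split_manifest(train: Sequence[ImagePair], test: Sequence[ImagePair], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "subset"])
        for p in train:
            writer.writerow([p.id, "train"])
        for p in test:
            writer.writerow([p.id, "test"])
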