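"""Image preprocessing and patch dataset construction for segmentation.

Full images are prepared by (1) green-channel extraction for RGB input,
(2) 0.5x downscaling, and (3) contrast-limited adaptive histogram
equalization (CLAHE, 8x8 tiles).  Training samples are square crops with
side drawn uniformly from 64-128 px, resized to 64x64 (labels by nearest
neighbor), optionally augmented (rotation, shear, translation, motion
blur on the intensity only), and finally normalized per patch to zero
mean and unit variance (constant patches are left as zeros).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.exposure import equalize_adapthist
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "preprocess",
    "extract_patches",
    "augment",
    "normalize_patch",
    "PatchDataset",
]

PATCH = 64


@dataclass
class PatchDataset:
    """Normalized 64x64 patches with binary labels and provenance."""

    patches: np.ndarray            # (N, 64, 64) float32, per-patch normalized
    labels: np.ndarray             # (N, 64, 64) uint8 in {0, 1}
    provenance: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)


def preprocess(
    image: np.ndarray,
    clahe_clip: float = 2.0,
    clahe_tiles: int = 8,
    downscale: float = 0.5,
) -> np.ndarray:
    """Standard full-image preparation: green channel, 0.5x resize, CLAHE.

    ``clahe_clip`` follows the familiar OpenCV convention (contrast limit in
    histogram-count multiples, default 2.0) and is converted internally to
    the normalized clip limit of ``skimage.exposure.equalize_adapthist``.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., 1]
    elif img.ndim != 2:
        raise TypeError(f"expected 2-D or RGB image, got shape {img.shape}")
    img = img.astype(np.float64)
    if img.max() > 1.0:
        img = img / img.max()
    h, w = img.shape
    out_shape = (max(int(round(h * downscale)), 1), max(int(round(w * downscale)), 1))
    img = resize(img, out_shape, order=1, anti_aliasing=True)
    if img.max() - img.min() < 1e-12:
        return img  # constant image: nothing to equalize
    tile = (max(img.shape[0] // clahe_tiles, 1), max(img.shape[1] // clahe_tiles, 1))
    return equalize_adapthist(np.clip(img, 0, 1), kernel_size=tile,
                              clip_limit=clahe_clip / 256.0)


def normalize_patch(patch: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Zero-mean unit-variance normalization; constant patches become zeros."""
    p = patch.astype(np.float64)
    mu = p.mean()
    sd = p.std()
    if sd < tol:
        return np.zeros_like(p)
    return (p - mu) / sd


def _affine(patch: np.ndarray, label: np.ndarray, rotation_deg: float,
            shear: float, translation: tuple[float, float]):
    """Apply one affine map (about the patch center) to patch and label."""
    c = (patch.shape[1] - 1) / 2.0, (patch.shape[0] - 1) / 2.0
    theta = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    shr = np.array([[1, shear, 0], [0, 1, 0], [0, 0, 1]])
    to_c = np.array([[1, 0, -c[0]], [0, 1, -c[1]], [0, 0, 1]])
    from_c = np.array([[1, 0, c[0] + translation[0]],
                       [0, 1, c[1] + translation[1]], [0, 0, 1]])
    m = from_c @ shr @ rot @ to_c
    tf = AffineTransform(matrix=m)
    out_p = warp(patch, tf.inverse, order=1, mode="reflect", preserve_range=True)
    out_l = warp(label.astype(float), tf.inverse, order=0, mode="constant",
                 cval=0, preserve_range=True)
    return out_p, (out_l > 0.5).astype(label.dtype)


def augment(
    patch: np.ndarray,
    label: np.ndarray,
    ops: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
    p_apply: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Random (or explicit) patch augmentation.

    ``ops`` may fix the parameters: keys ``rotation`` (deg), ``shear``,
    ``translation`` (dx, dy px), ``blur`` ((length_px, angle_rad) or None).
    Otherwise each augmentation is drawn independently with probability
    ``p_apply``: rotation +-30 deg, shear +-0.2, translation +-8 px, linear
    motion blur of length 3-9 px at a random angle.  Geometry is applied
    identically to patch and label; blur touches the intensity only and the
    label is re-binarized.
    """
    rng = np.random.default_rng() if rng is None else rng
    if ops is None:
        ops = {
            "rotation": rng.uniform(-30, 30) if rng.random() < p_apply else 0.0,
            "shear": rng.uniform(-0.2, 0.2) if rng.random() < p_apply else 0.0,
            "translation": tuple(rng.uniform(-8, 8, 2)) if rng.random() < p_apply else (0.0, 0.0),
            "blur": (rng.uniform(3, 9), rng.uniform(0, np.pi)) if rng.random() < p_apply else None,
        }
    rotation = ops.get("rotation", 0.0)
    shear = ops.get("shear", 0.0)
    translation = tuple(ops.get("translation", (0.0, 0.0)))
    if rotation or shear or any(translation):
        patch, label = _affine(patch, label, rotation, shear, translation)
    blur = ops.get("blur")
    if blur is not None:
        length, angle = blur
        n = max(int(round(length)), 1)
        k = np.zeros((2 * n + 1, 2 * n + 1))
        t = np.linspace(-(n - 1) / 2.0, (n - 1) / 2.0, max(4 * n, 2))
        k[np.round(n + t * np.sin(angle)).astype(int),
          np.round(n + t * np.cos(angle)).astype(int)] = 1.0
        patch = ndimage.convolve(patch, k / k.sum(), mode="reflect")
    return patch, label


def extract_patches(
    image: np.ndarray,
    label: np.ndarray,
    n: int,
    size_range: tuple[int, int] = (64, 128),
    seed: int = 0,
    augment_prob: float = 0.0,
    source_id: str = "",
) -> PatchDataset:
    """Random multi-scale square crops resized to 64x64 and normalized.

    Crop side is uniform over ``size_range``; the intensity patch is resized
    bilinearly and the label by nearest neighbor (then re-binarized).  With
    ``augment_prob`` > 0 each patch is additionally augmented with that
    per-operation probability.  Fully reproducible given ``seed``.
    """
    image = np.asarray(image, dtype=np.float64)
    label = (np.asarray(label) > 0).astype(np.uint8)
    if image.shape != label.shape:
        raise ValueError("image and label must share a shape")
    lo, hi = size_range
    if image.shape[0] < hi or image.shape[1] < hi:
        raise ValueError(f"image {image.shape} smaller than max crop size {hi}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    patches = np.empty((n, PATCH, PATCH), dtype=np.float32)
    labels = np.empty((n, PATCH, PATCH), dtype=np.uint8)
    provenance = []
    for i in range(n):
        side = int(rng.integers(lo, hi + 1))
        r = int(rng.integers(0, image.shape[0] - side + 1))
        c = int(rng.integers(0, image.shape[1] - side + 1))
        p = image[r:r + side, c:c + side]
        q = label[r:r + side, c:c + side]
        if side != PATCH:
            p = resize(p, (PATCH, PATCH), order=1, anti_aliasing=side > PATCH)
            q = (resize(q.astype(float), (PATCH, PATCH), order=0,
                        preserve_range=True) > 0.5).astype(np.uint8)
        applied = None
        if augment_prob > 0:
            p, q = augment(p, q, rng=rng, p_apply=augment_prob)
            applied = "random"
        patches[i] = normalize_patch(p)
        labels[i] = q
        provenance.append({
            "source": source_id, "box": (r, c, side), "augment": applied,
        })
    return PatchDataset(patches=patches, labels=labels, provenance=provenance)
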