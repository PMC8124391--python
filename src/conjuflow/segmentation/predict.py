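"""Full-image inference by overlapped 64x64 tiling.

The network is trained on 64x64 patches; a full frame is segmented by
averaging the first ``average_n`` motion-corrected frames (temporal
averaging reveals faint vessels), preprocessing (0.5x + CLAHE), sliding a
64x64 window with 50% overlap, normalizing each tile exactly as in
training, and blending the per-pixel vessel probabilities across
overlapping tiles before thresholding at 0.5.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..io import FrameSequence
from .preprocess import PATCH, normalize_patch, preprocess
from .unet import AttentionUNet

__all__ = ["average_frames", "predict_full", "predict_probabilities"]


def average_frames(seq: FrameSequence, n: int = 30) -> np.ndarray:
    """Mean of the first ``n`` frames (all frames, with a warning, if fewer)."""
    if len(seq) < n:
        warnings.warn(f"only {len(seq)} frames available; averaging all of them")
        n = len(seq)
    return seq.frames[:n].mean(axis=0)


def predict_probabilities(model: AttentionUNet, image: np.ndarray,
                          batch: int = 32) -> np.ndarray:
    """Vessel probability map of a preprocessed image (any size)."""
    img = np.asarray(image, dtype=np.float64)
    stride = PATCH // 2
    h, w = img.shape
    ph = max(int(np.ceil(max(h - PATCH, 0) / stride)) * stride + PATCH, PATCH)
    pw = max(int(np.ceil(max(w - PATCH, 0) / stride)) * stride + PATCH, PATCH)
    padded = np.pad(img, ((0, ph - h), (0, pw - w)), mode="reflect")
    tiles, origins = [], []
    for r in range(0, ph - PATCH + 1, stride):
        for c in range(0, pw - PATCH + 1, stride):
            tiles.append(normalize_patch(padded[r:r + PATCH, c:c + PATCH]))
            origins.append((r, c))
    tiles = np.asarray(tiles, dtype=np.float32)
    acc = np.zeros((ph, pw))
    cnt = np.zeros((ph, pw))
    for i in range(0, len(tiles), batch):
        probs = model.forward(tiles[i:i + batch], training=False)[..., 1]
        for p, (r, c) in zip(probs, origins[i:i + batch]):
            acc[r:r + PATCH, c:c + PATCH] += p
            cnt[r:r + PATCH, c:c + PATCH] += 1.0
    return (acc / cnt)[:h, :w]


def predict_full(
    model: AttentionUNet,
    source: FrameSequence | np.ndarray,
    threshold: float = 0.5,
    average_n: int = 30,
    do_preprocess: bool = True,
) -> np.ndarray:
    """Binary vessel mask of a frame sequence (30-frame average) or image."""
    if isinstance(source, FrameSequence):
        image = average_frames(source, average_n)
    else:
        image = np.asarray(source)
    if do_preprocess:
        image = preprocess(image)
    return predict_probabilities(model, image) >= threshold
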