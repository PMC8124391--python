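"""Synthetic training data for scaled-down segmentation experiments.

Builds a patch dataset from rendered synthetic scenes: each scene is
temporally averaged, preprocessed like real data (0.5x + CLAHE), and paired
with its ground-truth vessel mask resampled to the preprocessed geometry.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from ..synthetic import SceneConfig, generate_scene
from .predict import average_frames
from .preprocess import PatchDataset, extract_patches, preprocess

__all__ = ["synthetic_image_pair", "synthetic_patch_dataset"]


def synthetic_image_pair(seed: int, n_vessels: int = 8,
                         frame_shape=(320, 448), snr: float = 10.0):
    """One preprocessed synthetic image and its matching binary label."""
    cfg = SceneConfig(
        frame_shape=frame_shape,
        n_frames=8,
        n_vessels=n_vessels,
        saccades={},
        drift_amplitude_px=0.0,
        blur_frames=(),
        snr=snr,
        seed=seed,
    )
    seq, gt = generate_scene(cfg)
    image = preprocess(average_frames(seq, n=len(seq)))
    label = resize(gt.mask.astype(float), image.shape, order=0,
                   preserve_range=True) > 0.5
    return image, label


def scaled_down_training_run(
    n_patches: int = 2000,
    epochs: int = 20,
    seed: int = 0,
    base_filters: int = 4,
    learning_rate: float = 1e-3,
    batch_size: int = 32,
):
    """CPU-scale training experiment on synthetic patches.

    Trains a narrow (base_filters=4) attention U-Net on ``n_patches``
    synthetic patches for ``epochs`` epochs with a 4:1 train/validation
    split, then segments a held-out synthetic scene (unseen seed) with the
    trained model and scores it against the ground-truth mask.

    Returns ``(model, history, heldout_dice)``.
    """
    from .predict import predict_full
    from .train import TrainConfig, dice_coefficient, train
    from .unet import UNetSpec, build_model

    dataset = synthetic_patch_dataset(n_patches, seed=seed)
    model = build_model(UNetSpec(base_filters=base_filters), seed=seed)
    cfg = TrainConfig(
        epochs=epochs,
        learning_rate=learning_rate,
        plateau_patience=min(15, epochs - 1),
        batch_size=batch_size,
        seed=seed,
    )
    model, history = train(model, dataset, cfg)

    image, label = synthetic_image_pair(seed * 1000 + 999)
    pred = predict_full(model, image, do_preprocess=False)
    heldout_dice = dice_coefficient(pred.astype(float), label.astype(float))
    return model, history, heldout_dice


def synthetic_patch_dataset(
    n_patches: int,
    seed: int = 0,
    n_scenes: int = 2,
    augment_prob: float = 0.25,
) -> PatchDataset:
    """A patch dataset drawn evenly from ``n_scenes`` synthetic scenes."""
    per_scene = int(np.ceil(n_patches / n_scenes))
    parts = []
    for s in range(n_scenes):
        image, label = synthetic_image_pair(seed * 1000 + s)
        parts.append(
            extract_patches(image, label, per_scene, seed=seed * 100 + s,
                            augment_prob=augment_prob, source_id=f"scene{s}")
        )
    patches = np.concatenate([p.patches for p in parts])[:n_patches]
    labels = np.concatenate([p.labels for p in parts])[:n_patches]
    prov = [pr for p in parts for pr in p.provenance][:n_patches]
    return PatchDataset(patches=patches, labels=labels, provenance=prov)
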