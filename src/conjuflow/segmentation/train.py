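"""Dice-loss training of the attention U-Net.

The loss is one minus the soft Dice coefficient

    Dice = (2 sum(p q) + eps) / (sum(p^2) + sum(q^2) + eps)

computed over all pixels of a batch (eps = 1e-6 guards empty masks), which
counteracts the heavy vessel/background class imbalance.  Optimization uses
Adam with a reduce-on-plateau schedule: when the validation loss has not
improved for ``patience`` epochs the learning rate is multiplied by
``plateau_factor``.  The returned model carries the best-on-validation
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import PatchDataset
from .unet import AttentionUNet

__all__ = ["TrainConfig", "dice_coefficient", "train", "train_val_split"]

EPS = 1e-6


@dataclass
class TrainConfig:
    """Training protocol; defaults follow the full-scale recipe
    (Adam at 5e-5, 150 epochs, plateau factor 0.1 / patience 15, 4:1 split)."""

    epochs: int = 150
    learning_rate: float = 5e-5
    plateau_factor: float = 0.1
    plateau_patience: int = 15
    val_fraction: float = 0.2
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.plateau_patience >= self.epochs:
            raise ValueError("patience must be smaller than the epoch count")


def dice_coefficient(pred: np.ndarray, truth: np.ndarray, eps: float = EPS) -> float:
    """Soft Dice overlap between a prediction in [0,1] and a binary truth."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    num = 2.0 * np.sum(pred * truth) + eps
    den = np.sum(pred * pred) + np.sum(truth * truth) + eps
    return float(num / den)


def _dice_loss_and_grad(p: np.ndarray, q: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss 1 - Dice over the batch and its gradient w.r.t. ``p``."""
    p64 = p.astype(np.float64)
    q64 = q.astype(np.float64)
    a = 2.0 * np.sum(p64 * q64) + EPS
    b = np.sum(p64 * p64) + np.sum(q64 * q64) + EPS
    dice = a / b
    grad = -(2.0 * q64 * b - a * 2.0 * p64) / (b * b)
    return float(1.0 - dice), grad.astype(np.float32)


def train_val_split(n: int, val_fraction: float = 0.2, seed: int = 0):
    """Shuffled index split; with the default fraction, a 4:1 train/val ratio."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_val = int(round(n * val_fraction))
    return idx[n_val:], idx[:n_val]


class _Adam:
    def __init__(self, params, lr):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _eval(model: AttentionUNet, patches, labels, batch: int):
    """Validation loss (1 - soft Dice) and hard Dice in inference mode."""
    soft_a = soft_b = 0.0
    hard_a = hard_b = 0.0
    for i in range(0, len(patches), batch):
        x = patches[i:i + batch]
        q = labels[i:i + batch].astype(np.float64)
        p = model.forward(x, training=False)[..., 1].astype(np.float64)
        soft_a += 2.0 * np.sum(p * q)
        soft_b += np.sum(p * p) + np.sum(q * q)
        ph = (p >= 0.5).astype(np.float64)
        hard_a += 2.0 * np.sum(ph * q)
        hard_b += np.sum(ph * ph) + np.sum(q * q)
    soft = (soft_a + EPS) / (soft_b + EPS)
    hard = (hard_a + EPS) / (hard_b + EPS)
    return 1.0 - soft, hard


def train(model: AttentionUNet, dataset: PatchDataset, cfg: TrainConfig):
    """Train in place; returns ``(model, history)``.

    ``history`` holds per-epoch train loss, validation loss, validation
    (hard) Dice and learning rate.  The best-on-validation weights are
    restored into the model before returning.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    tr, va = train_val_split(len(dataset), cfg.val_fraction, cfg.seed)
    if len(tr) == 0 or len(va) == 0:
        raise ValueError("dataset too small for the requested split")
    x_tr, y_tr = dataset.patches[tr], dataset.labels[tr]
    x_va, y_va = dataset.patches[va], dataset.labels[va]

    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(model.params(), cfg.learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_dice": [], "lr": []}
    best_loss = np.inf
    best_params = None
    stall = 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            x = x_tr[sel]
            q = y_tr[sel].astype(np.float32)
            probs = model.forward(x, training=True)
            loss, gp = _dice_loss_and_grad(probs[..., 1], q)
            dprobs = np.zeros_like(probs)
            dprobs[..., 1] = gp
            model.backward(dprobs)
            opt.step(model.grads())
            losses.append(loss)
        val_loss, val_dice = _eval(model, x_va, y_va, cfg.batch_size)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        history["val_dice"].append(float(val_dice))
        history["lr"].append(float(opt.lr))

        if val_loss < best_loss - 1e-4:
            best_loss = val_loss
            best_params = [p.copy() for p in model.params()]
            best_stats = [(m.bn.running_mean.copy(), m.bn.running_var.copy())
                          for m in model._modules() if hasattr(m, "bn")]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.plateau_patience:
                opt.lr *= cfg.plateau_factor
                stall = 0

    if best_params is not None:
        for p, bp in zip(model.params(), best_params):
            p[...] = bp
        bns = [m for m in model._modules() if hasattr(m, "bn")]
        for m, (rm, rv) in zip(bns, best_stats):
            m.bn.running_mean, m.bn.running_var = rm, rv
    return model, history
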