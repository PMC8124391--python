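"""A three-stage attention U-Net implemented in numpy.

The network follows the classic attention U-Net layout specialized to
vessel/background classification of 64x64 patches:

* encoder: three stages of two (3x3 conv, stride 1 -> batch norm -> ReLU)
  blocks followed by 2x2 max pooling, with the filter count doubling per
  stage, and a bottom stage without pooling;
* decoder: per stage, upsampling by a transposed 3x3 stride-2 convolution,
  an additive attention gate on the encoder skip connection (1x1
  projections of skip and gating signals, ReLU, 1x1 conv + sigmoid
  coefficient map multiplied onto the skip features), channel
  concatenation, and two conv-BN-ReLU blocks;
* head: a 1x1 convolution to two channels with per-pixel softmax over
  {background, vessel}.

All layers carry hand-written forward/backward passes; convolutions run as
im2col + BLAS matrix multiplies in float32, so training small models on a
CPU is practical.  Input spatial dimensions must be divisible by
``2**stages``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNetSpec", "AttentionUNet", "build_model", "attention_gate"]

F32 = np.float32


@dataclass(frozen=True)
class UNetSpec:
    """Architecture hyperparameters: number of stages and first-stage width."""

    stages: int = 3
    base_filters: int = 32
    in_channels: int = 1
    n_classes: int = 2


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv2D:
    """k x k convolution, stride 1, 'same' zero padding, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None, bias: bool = True):
        rng = np.random.default_rng() if rng is None else rng
        scale = np.sqrt(2.0 / (k * k * cin))
        self.W = (rng.standard_normal((k, k, cin, cout)) * scale).astype(F32)
        self.b = np.zeros(cout, dtype=F32) if bias else None
        self.k = k
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.dW] + ([self.db] if self.b is not None else [])

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        pad = k // 2
        if pad:
            x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        # windows over spatial dims: (N, H, W, C, k, k) -> (N*H*W, k*k*C)
        w = sliding_window_view(x, (k, k), axis=(1, 2))
        n, h, wd, c = w.shape[:4]
        return np.ascontiguousarray(w.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * wd, k * k * c), (n, h, wd)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        cols, (n, h, w) = self._im2col(x, self.k)
        wmat = self.W.reshape(-1, self.W.shape[-1])
        y = cols @ wmat
        if self.b is not None:
            y += self.b
        self._cache = (cols, x.shape)
        return y.reshape(n, h, w, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, h, w, cout = dy.shape
        dyf = dy.reshape(-1, cout)
        self.dW = (cols.T @ dyf).reshape(self.W.shape)
        if self.b is not None:
            self.db = dyf.sum(axis=0)
        # grad wrt input: correlate dy with spatially flipped, channel-swapped W
        wflip = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,cout,cin)
        cols2, _ = self._im2col(dy, self.k)
        dx = cols2 @ wflip.reshape(-1, wflip.shape[-1])
        return dx.reshape(xshape).astype(F32)


class BatchNorm:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat.astype(F32), inv.astype(F32), x.shape)
        return (self.gamma * xhat + self.beta).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[1] * shape[2]
        self.dgamma = np.sum(dy * xhat, axis=(0, 1, 2))
        self.dbeta = np.sum(dy, axis=(0, 1, 2))
        dxhat = dy * self.gamma
        dx = (dxhat - dxhat.mean(axis=(0, 1, 2))
              - xhat * np.mean(dxhat * xhat, axis=(0, 1, 2))) * inv
        return dx.astype(F32)


class ReLU:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, training=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class MaxPool2:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, training=True):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        self._cache = (xr, y)
        return y

    def backward(self, dy):
        xr, y = self._cache
        mask = (xr == y[:, :, None, :, None, :])
        counts = mask.sum(axis=(2, 4), keepdims=True)
        d = mask * (dy[:, :, None, :, None, :] / counts)
        n, hh, _, ww, _, c = xr.shape
        return d.reshape(n, hh * 2, ww * 2, c).astype(F32)


class UpConv:
    """Transposed 3x3 stride-2 convolution (zero-insert upsample + 3x3 conv)."""

    def __init__(self, cin: int, cout: int, rng=None):
        self.conv = Conv2D(cin, cout, k=3, rng=rng)

    def params(self):
        return self.conv.params()

    def grads(self):
        return self.conv.grads()

    def forward(self, x, training=True):
        n, h, w, c = x.shape
        up = np.zeros((n, 2 * h, 2 * w, c), dtype=F32)
        up[:, ::2, ::2, :] = x
        return self.conv.forward(up, training)

    def backward(self, dy):
        dup = self.conv.backward(dy)
        return dup[:, ::2, ::2, :]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class AttentionGate:
    """Additive attention gate on a skip connection.

    1x1-projects the skip features ``x`` and the gating signal ``g`` (same
    spatial size) to an intermediate width, adds, applies ReLU, maps to a
    single channel, squashes with a sigmoid, and multiplies the resulting
    coefficient map onto the skip features.
    """

    def __init__(self, c_skip: int, c_gate: int, c_int: int, rng=None):
        self.theta = Conv2D(c_skip, c_int, k=1, rng=rng, bias=False)
        self.phi = Conv2D(c_gate, c_int, k=1, rng=rng)
        self.psi = Conv2D(c_int, 1, k=1, rng=rng)

    def params(self):
        return self.theta.params() + self.phi.params() + self.psi.params()

    def grads(self):
        return self.theta.grads() + self.phi.grads() + self.psi.grads()

    def forward(self, x, g, training=True):
        t = self.theta.forward(x, training)
        p = self.phi.forward(g, training)
        self._pre = t + p
        a = np.where(self._pre > 0, self._pre, 0)
        s = _sigmoid(self.psi.forward(a, training))
        self._cache = (x, s)
        self.coefficients = s
        return (x * s).astype(F32)

    def backward(self, dy):
        x, s = self._cache
        dx_direct = dy * s
        ds = np.sum(dy * x, axis=3, keepdims=True)
        dpsi_out = ds * s * (1 - s)
        da = self.psi.backward(dpsi_out)
        da = np.where(self._pre > 0, da, 0)
        dx_gate = self.theta.backward(da)
        dg = self.phi.backward(da)
        return (dx_direct + dx_gate).astype(F32), dg.astype(F32)


class ConvBNReLU:
    def __init__(self, cin, cout, rng=None):
        self.conv = Conv2D(cin, cout, k=3, rng=rng, bias=False)
        self.bn = BatchNorm(cout)
        self.act = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def grads(self):
        return self.conv.grads() + self.bn.grads()

    def forward(self, x, training=True):
        return self.act.forward(self.bn.forward(self.conv.forward(x, training), training))

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.act.backward(dy)))


def attention_gate(skip_features: np.ndarray, gating_features: np.ndarray,
                   c_int: int | None = None, rng=None) -> np.ndarray:
    """Functional attention-gate application (fresh random projections).

    Provided for inspection/testing of the gating mechanism; inside the
    network the gates are learned layers.
    """
    cs = skip_features.shape[-1]
    cg = gating_features.shape[-1]
    gate = AttentionGate(cs, cg, c_int or max(cs // 2, 1), rng=rng)
    return gate.forward(skip_features, gating_features, training=False)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class AttentionUNet:
    def __init__(self, spec: UNetSpec = UNetSpec(), seed: int = 0):
        if spec.stages < 1:
            raise ValueError("need at least one stage")
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = spec.base_filters
        s = spec.stages
        widths = [f * 2 ** i for i in range(s + 1)]  # stage widths + bottom

        self.enc = []
        cin = spec.in_channels
        for i in range(s):
            self.enc.append([ConvBNReLU(cin, widths[i], rng), ConvBNReLU(widths[i], widths[i], rng)])
            cin = widths[i]
        self.pools = [MaxPool2() for _ in range(s)]
        self.bottom = [ConvBNReLU(widths[s - 1], widths[s], rng),
                       ConvBNReLU(widths[s], widths[s], rng)]

        self.ups, self.gates, self.dec = [], [], []
        cin = widths[s]
        for i in reversed(range(s)):
            self.ups.append(UpConv(cin, widths[i], rng))
            self.gates.append(AttentionGate(widths[i], widths[i], max(widths[i] // 2, 1), rng))
            self.dec.append([ConvBNReLU(2 * widths[i], widths[i], rng),
                             ConvBNReLU(widths[i], widths[i], rng)])
            cin = widths[i]
        self.head = Conv2D(widths[0], spec.n_classes, k=1, rng=rng)

    # -- plumbing ---------------------------------------------------------

    def _modules(self):
        for blocks in self.enc:
            yield from blocks
        yield from self.bottom
        for up, gate, blocks in zip(self.ups, self.gates, self.dec):
            yield up
            yield gate
            yield from blocks
        yield self.head

    def params(self) -> list[np.ndarray]:
        out = []
        for m in self._modules():
            out.extend(m.params())
        return out

    def grads(self) -> list[np.ndarray]:
        out = []
        for m in self._modules():
            out.extend(m.grads())
        return out

    def count_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """Map (N, H, W, Cin) to per-pixel class probabilities (N, H, W, 2)."""
        x = np.asarray(x, dtype=F32)
        if x.ndim == 3:
            x = x[..., None]
        div = 2 ** self.spec.stages
        if x.shape[1] % div or x.shape[2] % div:
            raise ValueError(f"spatial dims must be divisible by {div}, got {x.shape[1:3]}")
        skips = []
        h = x
        for blocks, pool in zip(self.enc, self.pools):
            for b in blocks:
                h = b.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        for b in self.bottom:
            h = b.forward(h, training)
        for up, gate, blocks, skip in zip(self.ups, self.gates, self.dec, reversed(skips)):
            g = up.forward(h, training)
            gated = gate.forward(skip, g, training)
            h = np.concatenate([gated, g], axis=3)
            for b in blocks:
                h = b.forward(h, training)
        logits = self.head.forward(h, training)
        z = logits - logits.max(axis=3, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=3, keepdims=True)
        self._probs = probs.astype(F32)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the softmax output."""
        p = self._probs
        inner = np.sum(dprobs * p, axis=3, keepdims=True)
        dlogits = (p * (dprobs - inner)).astype(F32)
        h = self.head.backward(dlogits)
        for up, gate, blocks in zip(reversed(self.ups), reversed(self.gates),
                                    reversed(self.dec)):
            for b in reversed(blocks):
                h = b.backward(h)
            c = gate._cache[0].shape[-1]
            dgated, dg_up = h[..., :c], h[..., c:]
            dskip, dgate_g = gate.backward(dgated)
            dh = up.backward(dg_up + dgate_g)
            # dskip is consumed when unwinding the matching encoder stage
            up._dskip = dskip
            h = dh
        for blocks in reversed(self.bottom):
            h = blocks.backward(h)
        for blocks, pool, up in zip(reversed(self.enc), reversed(self.pools), self.ups):
            h = pool.backward(h) + up._dskip
            for b in reversed(blocks):
                h = b.backward(h)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save weights (npz) plus an architecture JSON next to it."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p for i, p in enumerate(self.params())}
        stats = {}
        for j, m in enumerate(self._modules()):
            if isinstance(m, ConvBNReLU):
                stats[f"rm{j}"] = m.bn.running_mean
                stats[f"rv{j}"] = m.bn.running_var
        np.savez(path, **arrays, **stats)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.spec)))

    @classmethod
    def load(cls, path: str | Path) -> "AttentionUNet":
        path = Path(path)
        spec = UNetSpec(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(spec)
        data = np.load(path)
        for i, p in enumerate(model.params()):
            p[...] = data[f"p{i}"]
        for j, m in enumerate(model._modules()):
            if isinstance(m, ConvBNReLU) and f"rm{j}" in data:
                m.bn.running_mean = data[f"rm{j}"]
                m.bn.running_var = data[f"rv{j}"]
        return model


def build_model(spec: UNetSpec = UNetSpec(), seed: int = 0) -> AttentionUNet:
    """Construct an :class:`AttentionUNet` from an architecture spec."""
    return AttentionUNet(spec, seed=seed)
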