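"""A compact 2-D U-Net written directly on numpy.

Encoder–decoder with skip connections, single-channel input and a
single-channel probability output.  Convolutions are 3×3 (stride 1,
zero-padded) computed by im2col + matrix multiply; downsampling is 2×2 max
pooling, upsampling is nearest-neighbour ×2 followed by a 3×3 convolution
that halves the channel count.  Every block is two conv+ReLU layers.

For depth d and base filter count f the channel widths are
f, 2f, …, 2^d·f at the bottleneck, so the parameter count is the exact
closed form implemented in `n_params` (each 3×3 conv a→b contributes
9ab + b parameters, the final 1×1 conv f + 1).

Training uses Adam on a soft-Dice + voxelwise binary-cross-entropy loss
(equal weights); the Dice term keeps the loss informative under the heavy
class imbalance of tumor masks.  Inputs whose height/width are not
divisible by 2^depth are rejected with the padding that would be required
— nothing is padded silently.

All arithmetic is float32; initialisation and shuffling are driven by an
explicit seed, so identical configs and data reproduce identical weights.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np

__all__ = ["UNet", "Adam", "dice_bce_loss", "n_params", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Conv3x3:
    """3×3 same-padding convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = (rng.standard_normal((c_out, c_in * 9)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # (n, c, h, w, 3, 3) -> (n*h*w, c*9): one flat GEMM over the batch
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)
        self._cols, self._shape = cols, (n, c, h, w)
        out = cols @ self.W.T + self.b
        return out.reshape(n, h * w, self.c_out).transpose(0, 2, 1).reshape(n, self.c_out, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.ascontiguousarray(
            dout.reshape(n, self.c_out, h * w).transpose(0, 2, 1)
        ).reshape(n * h * w, self.c_out)
        self.dW = (dflat.T @ self._cols).astype(np.float32)
        self.db = dflat.sum(axis=0).astype(np.float32)
        dcols = (dflat @ self.W).reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, 1 : h + 1, 1 : w + 1]

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class _Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.W = (rng.standard_normal((c_out, c_in)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        out = self.W @ x.transpose(1, 0, 2, 3).reshape(c, n * h * w)
        return out.reshape(-1, n, h, w).transpose(1, 0, 2, 3) + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x.shape
        f = dout.shape[1]
        dflat = dout.transpose(1, 0, 2, 3).reshape(f, n * h * w)
        xflat = self._x.transpose(1, 0, 2, 3).reshape(c, n * h * w)
        self.dW = (dflat @ xflat.T).astype(np.float32)
        self.db = dflat.sum(axis=1).astype(np.float32)
        dx = (self.W.T @ dflat).reshape(c, n, h, w).transpose(1, 0, 2, 3)
        self._x = None
        return dx

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


def _relu_fwd(x):
    mask = x > 0
    return x * mask, mask


def _maxpool_fwd(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _maxpool_bwd(dout, cache):
    idx, (n, c, h, w) = cache
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return (
        dxr.reshape(n, c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )


def _upsample_fwd(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample_bwd(dout):
    n, c, h2, w2 = dout.shape
    return dout.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


def n_params(depth: int, base_filters: int, in_channels: int = 1) -> int:
    """Closed-form parameter count of this topology."""

    def conv3(a, b):
        return 9 * a * b + b

    widths = [base_filters * 2**i for i in range(depth + 1)]
    total = 0
    prev = in_channels
    for i in range(depth):  # encoder double-convs
        total += conv3(prev, widths[i]) + conv3(widths[i], widths[i])
        prev = widths[i]
    total += conv3(prev, widths[depth]) + conv3(widths[depth], widths[depth])
    for i in reversed(range(depth)):  # up-conv + decoder double-convs
        total += conv3(widths[i + 1], widths[i])
        total += conv3(2 * widths[i], widths[i]) + conv3(widths[i], widths[i])
    total += widths[0] + 1  # final 1x1 conv
    return total


class UNet:
    """2-D U-Net returning voxelwise logits; `predict_proba` applies sigmoid."""

    def __init__(self, depth: int = 3, base_filters: int = 8, seed: int = 0, in_channels: int = 1):
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
        if base_filters < 1:
            raise ValueError(f"base_filters must be >= 1, got {base_filters}")
        self.depth, self.base_filters, self.in_channels = depth, base_filters, in_channels
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = [base_filters * 2**i for i in range(depth + 1)]
        self.enc: list[list[_Conv3x3]] = []
        prev = in_channels
        for i in range(depth):
            self.enc.append([_Conv3x3(prev, widths[i], rng), _Conv3x3(widths[i], widths[i], rng)])
            prev = widths[i]
        self.bottleneck = [_Conv3x3(prev, widths[depth], rng), _Conv3x3(widths[depth], widths[depth], rng)]
        self.upconv: list[_Conv3x3] = []
        self.dec: list[list[_Conv3x3]] = []
        for i in reversed(range(depth)):
            self.upconv.append(_Conv3x3(widths[i + 1], widths[i], rng))
            self.dec.append([_Conv3x3(2 * widths[i], widths[i], rng), _Conv3x3(widths[i], widths[i], rng)])
        self.final = _Conv1x1(widths[0], 1, rng)

    # ---- plumbing -------------------------------------------------------

    def _layers(self):
        for block in self.enc:
            yield from block
        yield from self.bottleneck
        for up, block in zip(self.upconv, self.dec):
            yield up
            yield from block
        yield self.final

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(layer.grads)
        return out

    def set_parameters(self, values: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(values) != len(params):
            raise ValueError("parameter list length mismatch")
        for layer in self._layers():
            if hasattr(layer, "W"):
                layer.W = values.pop(0).astype(np.float32).reshape(layer.W.shape)
                layer.b = values.pop(0).astype(np.float32).reshape(layer.b.shape)
        # note: values was consumed pairwise in layer order

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def check_input(self, h: int, w: int) -> None:
        div = 2**self.depth
        if h % div or w % div:
            need_h = (div - h % div) % div
            need_w = (div - w % div) % div
            raise ValueError(
                f"tile size {h}×{w} incompatible with depth {self.depth}: "
                f"height and width must be divisible by {div}; pad by "
                f"({need_h}, {need_w})"
            )

    # ---- forward / backward --------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch (N, C, H, W); caches activations for backward."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected input (N, {self.in_channels}, H, W), got {x.shape}")
        self.check_input(x.shape[2], x.shape[3])
        self._relu_masks = []
        self._pool_caches = []
        self._skip_channels = []
        h = x
        skips = []
        for block in self.enc:
            for conv in block:
                h, m = _relu_fwd(conv.forward(h))
                self._relu_masks.append(m)
            skips.append(h)
            h, cache = _maxpool_fwd(h)
            self._pool_caches.append(cache)
        for conv in self.bottleneck:
            h, m = _relu_fwd(conv.forward(h))
            self._relu_masks.append(m)
        for level, (up, block) in enumerate(zip(self.upconv, self.dec)):
            h = _upsample_fwd(h)
            h, m = _relu_fwd(up.forward(h))
            self._relu_masks.append(m)
            skip = skips[self.depth - 1 - level]
            self._skip_channels.append((skip.shape[1], h.shape[1]))
            h = np.concatenate([skip, h], axis=1)
            for conv in block:
                h, m = _relu_fwd(conv.forward(h))
                self._relu_masks.append(m)
        return self.final.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        masks = list(self._relu_masks)
        pools = list(self._pool_caches)
        skipch = list(self._skip_channels)
        d = self.final.backward(dlogits.astype(np.float32))
        dskips: list[np.ndarray | None] = [None] * self.depth
        for idx in reversed(range(self.depth)):  # dec[idx] pairs with encoder level depth-1-idx
            for conv in reversed(self.dec[idx]):
                d = conv.backward(d * masks.pop())
            c_skip, _ = skipch.pop()
            dskip, d = d[:, :c_skip], d[:, c_skip:]
            dskips[self.depth - 1 - idx] = dskip
            d = self.upconv[idx].backward(d * masks.pop())
            d = _upsample_bwd(d)
        for conv in reversed(self.bottleneck):
            d = conv.backward(d * masks.pop())
        for i in reversed(range(self.depth)):
            d = _maxpool_bwd(d, pools.pop())
            d = d + dskips[i]
            for conv in reversed(self.enc[i]):
                d = conv.backward(d * masks.pop())
        self._relu_masks = []
        self._pool_caches = []

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Sigmoid probabilities for a stack of tiles, batched."""
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(sigmoid(self.forward(x[i : i + batch_size])))
        self._relu_masks = []
        self._pool_caches = []
        return np.concatenate(outs, axis=0)

    # ---- checkpointing --------------------------------------------------

    def save(self, path, extra: dict | None = None) -> None:
        meta = {
            "depth": self.depth,
            "base_filters": self.base_filters,
            "in_channels": self.in_channels,
            "seed": self.seed,
            "extra": extra or {},
        }
        arrays = {f"p{i:03d}": p for i, p in enumerate(self.parameters())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> tuple["UNet", dict]:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            model = cls(
                depth=meta["depth"],
                base_filters=meta["base_filters"],
                seed=meta["seed"],
                in_channels=meta["in_channels"],
            )
            values = [data[f"p{i:03d}"] for i in range(len(model.parameters()))]
        model.set_parameters(values)
        return model, meta["extra"]


def dice_bce_loss(logits: np.ndarray, targets: np.ndarray, smooth: float = 1.0):
    """Soft-Dice + binary cross-entropy (equal weights) and its gradient.

    Returns (loss, dloss/dlogits).  The Dice term is computed over the
    whole batch, which stabilises it on slices with few or no foreground
    voxels.
    """
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    n = z.size
    p = sigmoid(z)
    bce = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    dbce = (p - t) / n

    s_pt, s_p, s_t = (p * t).sum(), p.sum(), t.sum()
    denom = s_p + s_t + smooth
    dice = (2 * s_pt + smooth) / denom
    ddice_dp = (2 * t * denom - (2 * s_pt + smooth)) / denom**2
    dl_dp = -ddice_dp
    dloss = dbce + dl_dp * p * (1 - p)
    loss = bce + (1.0 - dice)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss (NaN/Inf)")
    return float(loss), dloss.astype(np.float32)


class Adam:
    """Standard Adam; state arrays match the model's parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
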