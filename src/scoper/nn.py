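"""Minimal neural-network engine for the two classifiers in this package.

Two models are needed and both are small enough to train on a single CPU:

* a single-hidden-layer feedforward network (sigmoid hidden units, softmax
  output) trained full-batch with conjugate-gradient backpropagation
  (:class:`FeedForwardNet`), used by the sleep stager;
* a residual convolutional network whose building block computes
  ``y_i = H_i(x_i) + x_i`` with ``H_i`` a conv-ReLU-conv stage
  (:class:`ResidualCNN`), trained with Adam on a weighted binary
  cross-entropy, used by the apnea detector.

Everything is plain numpy; determinism is guaranteed by seeding the
initialization and the minibatch shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["FeedForwardNet", "ResidualCNN", "residual_layers_for_depth"]


# --------------------------------------------------------------------- FFNN


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class FeedForwardNet:
    """Single-hidden-layer FFNN: sigmoid hidden units, softmax output,
    trained full-batch with a conjugate-gradient optimizer."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, seed: int = 0, l2: float = 1e-4):
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out
        self.l2 = l2
        rng = np.random.default_rng(seed)
        s1 = np.sqrt(2.0 / (n_in + n_hidden))
        s2 = np.sqrt(2.0 / (n_hidden + n_out))
        self.w1 = rng.normal(0, s1, (n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.w2 = rng.normal(0, s2, (n_hidden, n_out))
        self.b2 = np.zeros(n_out)

    # -- parameter vector packing
    def _pack(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2.ravel(), self.b2])

    def _unpack(self, theta: np.ndarray) -> None:
        i = 0
        for name, shape in (
            ("w1", (self.n_in, self.n_hidden)),
            ("b1", (self.n_hidden,)),
            ("w2", (self.n_hidden, self.n_out)),
            ("b2", (self.n_out,)),
        ):
            size = int(np.prod(shape))
            setattr(self, name, theta[i : i + size].reshape(shape))
            i += size

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        h = 1.0 / (1.0 + np.exp(-(x @ self.w1 + self.b1)))
        return _softmax(h @ self.w2 + self.b2)

    def _loss_grad(self, theta, x, y_onehot):
        self._unpack(theta)
        n = x.shape[0]
        a1 = x @ self.w1 + self.b1
        h = 1.0 / (1.0 + np.exp(-a1))
        p = _softmax(h @ self.w2 + self.b2)
        eps = 1e-12
        loss = -np.sum(y_onehot * np.log(p + eps)) / n
        loss += 0.5 * self.l2 * (np.sum(self.w1**2) + np.sum(self.w2**2))
        d2 = (p - y_onehot) / n
        gw2 = h.T @ d2 + self.l2 * self.w2
        gb2 = d2.sum(axis=0)
        dh = d2 @ self.w2.T * h * (1 - h)
        gw1 = x.T @ dh + self.l2 * self.w1
        gb1 = dh.sum(axis=0)
        grad = np.concatenate([gw1.ravel(), gb1, gw2.ravel(), gb2])
        return loss, grad

    def fit(self, x: np.ndarray, labels: np.ndarray, max_iter: int = 500) -> "FeedForwardNet":
        """Conjugate-gradient training on integer class labels."""
        x = np.asarray(x, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if np.unique(labels).size < 2:
            raise ValueError("need at least two classes to train")
        y = np.zeros((labels.size, self.n_out))
        y[np.arange(labels.size), labels] = 1.0
        res = minimize(
            self._loss_grad,
            self._pack(),
            args=(x, y),
            jac=True,
            method="CG",
            options={"maxiter": max_iter, "gtol": 1e-7},
        )
        self._unpack(res.x)
        return self


# ------------------------------------------------------------- residual CNN


def _conv_cols(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """Gather k x k patches of a padded NCHW tensor into
    (N, C, k, k, Ho, Wo) without copying more than 9 slices."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, ki, kj] = xp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride]
    return cols


class _Conv:
    """k x k convolution, SAME padding for k=3 / none for k=1."""

    def __init__(self, c_in, c_out, k, stride, rng):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = rng.normal(0, scale, (c_out, c_in * k * k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.stride, self.pad = k, stride, (k // 2)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = _conv_cols(xp, k, s, ho, wo).reshape(n, c * k * k, ho * wo)
        out = np.einsum("fk,nkm->nfm", self.w, cols, optimize=True)
        out += self.b[None, :, None]
        self._cache = (x.shape, cols, ho, wo)
        return out.reshape(n, -1, ho, wo)

    def backward(self, dout):
        (xshape, cols, ho, wo) = self._cache
        n, c, h, w = xshape
        p, k, s = self.pad, self.k, self.stride
        dflat = dout.reshape(n, -1, ho * wo)
        self.gw += np.einsum("nfm,nkm->fk", dflat, cols, optimize=True)
        self.gb += dflat.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfm->nkm", self.w, dflat, optimize=True)
        dcols = dcols.reshape(n, c, k, k, ho, wo)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[:, :, ki, kj]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class _ResBlock:
    """y = H(x) + shortcut(x) with H = conv3 -> ReLU -> conv3.

    The shortcut is the identity when shape is preserved, otherwise a
    strided 1x1 projection.  With all-zero weights an identity-shortcut
    block is exactly the identity map.
    """

    def __init__(self, c_in, c_out, stride, rng):
        self.conv1 = _Conv(c_in, c_out, 3, stride, rng)
        self.conv2 = _Conv(c_out, c_out, 3, 1, rng)
        self.proj = None
        if stride != 1 or c_in != c_out:
            self.proj = _Conv(c_in, c_out, 1, stride, rng)

    def forward(self, x):
        a = self.conv1.forward(x)
        self._mask = a > 0
        h = self.conv2.forward(a * self._mask)
        sc = self.proj.forward(x) if self.proj is not None else x
        return h + sc

    def backward(self, dout):
        da = self.conv2.backward(dout) * self._mask
        dx = self.conv1.backward(da)
        if self.proj is not None:
            dx = dx + self.proj.backward(dout)
        else:
            dx = dx + dout
        return dx

    def params(self):
        out = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out


def residual_layers_for_depth(total_layers: int) -> int:
    """Number of residual blocks giving ~`total_layers` weighted layers
    (stem + 2 per block + head)."""
    return max(1, (total_layers - 2) // 2)


class ResidualCNN:
    """Residual CNN mapping a (raster x raster) scalogram image to an
    apnea-confidence score in [0, 1].

    Desk-scale default: 8 residual blocks (~18 weighted layers) with the
    channel width doubling and the resolution halving every second block;
    the deep 115-layer configuration of the original design is available
    via ``ResidualCNN(n_blocks=residual_layers_for_depth(115))``.
    """

    def __init__(
        self,
        raster: int = 32,
        n_blocks: int = 8,
        c0: int = 8,
        seed: int = 0,
        stem_stride: int = 2,
    ):
        if n_blocks < 1:
            raise ValueError("need at least one residual block")
        rng = np.random.default_rng(seed)
        self.raster, self.n_blocks = raster, n_blocks
        # strided stem: halves the working resolution up front, which cuts
        # the cost of the early blocks fourfold
        self.stem = _Conv(1, c0, 3, stem_stride, rng)
        self.blocks = []
        c = c0
        size = raster // stem_stride
        for i in range(n_blocks):
            stride = 1
            c_out = c
            if i > 0 and i % 2 == 0 and size > 4:
                stride, c_out = 2, min(c * 2, 64)
                size //= 2
            self.blocks.append(_ResBlock(c, c_out, stride, rng))
            c = c_out
        self.head_w = rng.normal(0, np.sqrt(1.0 / (2 * c)), (2 * c, 1)).astype(np.float32)
        self.head_b = np.zeros(1, dtype=np.float32)
        self.head_gw = np.zeros_like(self.head_w)
        self.head_gb = np.zeros_like(self.head_b)
        self._seed = seed

    # ---- forward / backward
    def _forward(self, x):
        z = self.stem.forward(x)
        for blk in self.blocks:
            z = blk.forward(z)
        self._feat_shape = z.shape
        n, c, h, w = z.shape
        flat = z.reshape(n, c, h * w)
        self._argmax = flat.argmax(axis=2)
        # global average + max pooling: the mean branch summarizes the
        # whole epoch, the max branch keeps localized (edge-of-epoch) cues
        feat = np.concatenate([flat.mean(axis=2), flat.max(axis=2)], axis=1)
        self._feat = feat
        logits = feat @ self.head_w + self.head_b
        return logits[:, 0]

    def _backward(self, dlogits):
        self.head_gw += self._feat.T @ dlogits[:, None]
        self.head_gb += dlogits.sum(keepdims=True)
        dfeat = dlogits[:, None] @ self.head_w.T
        n, c, h, w = self._feat_shape
        dz = np.broadcast_to(
            dfeat[:, :c, None, None] / (h * w), self._feat_shape
        ).astype(np.float32).copy()
        dz_flat = dz.reshape(n, c, h * w)
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        dz_flat[ni, ci, self._argmax] += dfeat[:, c:]
        for blk in reversed(self.blocks):
            dz = blk.backward(dz)
        self.stem.backward(dz)

    def _params(self):
        out = self.stem.params()
        for blk in self.blocks:
            out += blk.params()
        out.append((self.head_w, self.head_gw))
        out.append((self.head_b, self.head_gb))
        return out

    def parameter_count(self) -> int:
        return int(sum(p.size for p, _ in self._params()))

    def predict(self, images: np.ndarray, batch: int = 256) -> np.ndarray:
        """Confidence scores in [0, 1] for (n, raster, raster) images."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        x = x[:, None, :, :]
        out = []
        for i in range(0, x.shape[0], batch):
            logits = np.clip(self._forward(x[i : i + batch]), -60, 60)
            out.append(1.0 / (1.0 + np.exp(-logits)))
        return np.concatenate(out)

    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        epochs: int = 30,
        batch: int = 64,
        lr: float = 3e-3,
        weight_positive: float | None = None,
        weight_decay: float = 1e-4,
        augment: bool = True,
    ) -> "ResidualCNN":
        """Adam training on weighted binary cross-entropy.

        Class imbalance is handled by weighting the positive class by the
        negative/positive prevalence ratio unless given explicitly; with
        ``augment`` the training set is doubled by time-axis flips.
        Deterministic for a fixed construction seed.
        """
        x = np.asarray(images, dtype=np.float32)[:, None, :, :]
        y = np.asarray(labels, dtype=np.float32)
        if augment:
            x = np.concatenate([x, x[:, :, :, ::-1]])
            y = np.concatenate([y, y])
        if np.unique(y).size < 2:
            raise ValueError("need both classes to train")
        if weight_positive is None:
            pos = max(1.0, float(y.sum()))
            weight_positive = float((y.size - pos) / pos)
        rng = np.random.default_rng(self._seed + 1)
        params = self._params()
        m = [np.zeros_like(p) for p, _ in params]
        v = [np.zeros_like(p) for p, _ in params]
        step = 0
        for _ in range(epochs):
            order = rng.permutation(x.shape[0])
            for i in range(0, x.shape[0], batch):
                idx = order[i : i + batch]
                xb, yb = x[idx], y[idx]
                for _, g in params:
                    g[...] = 0.0
                logits = np.clip(self._forward(xb), -60, 60)
                p = 1.0 / (1.0 + np.exp(-logits))
                wgt = np.where(yb > 0.5, weight_positive, 1.0).astype(np.float32)
                wgt /= wgt.sum()
                dlogits = ((p - yb) * wgt).astype(np.float32)
                self._backward(dlogits)
                step += 1
                b1, b2, eps = 0.9, 0.999, 1e-8
                for j, (pa, g) in enumerate(params):
                    m[j] = b1 * m[j] + (1 - b1) * g
                    v[j] = b2 * v[j] + (1 - b2) * g * g
                    mh = m[j] / (1 - b1**step)
                    vh = v[j] / (1 - b2**step)
                    pa -= lr * (mh / (np.sqrt(vh) + eps) + weight_decay * pa)
        return self
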