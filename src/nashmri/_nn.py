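"""Minimal numpy neural-network layers with hand-written backprop.

Sized for desk-scale medical-image work (64x64 slices, 16x16 patches):
im2col convolutions, nearest-neighbour upsampling, Adam. Everything is
deterministic given the ``numpy.random.Generator`` used at construction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base: parametric layers expose ``params()`` -> list of (value, grad) names."""

    def params(self):
        return []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution via im2col; NCHW layout; He-initialised."""

    def __init__(self, cin, cout, k=3, stride=1, pad=1, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.standard_normal((cout, cin * k * k)) * scale
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout

    def params(self):
        return [("W", self), ("b", self)]

    def forward(self, x):
        self.xshape = x.shape
        n, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        v = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        v = v[:, :, :: self.stride, :: self.stride]
        self.hout, self.wout = v.shape[2], v.shape[3]
        cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(
            n, self.hout * self.wout, c * self.k * self.k
        )
        self.cols = cols
        y = cols @ self.W.T + self.b
        return np.ascontiguousarray(
            y.reshape(n, self.hout, self.wout, self.cout).transpose(0, 3, 1, 2)
        )

    def backward(self, dy):
        n, c = self.xshape[0], self.xshape[1]
        dyf = dy.transpose(0, 2, 3, 1).reshape(n, -1, self.cout)
        self.dW = np.einsum("npo,npc->oc", dyf, self.cols)
        self.db = dyf.sum(axis=(0, 1))
        dcols = dyf @ self.W
        d = dcols.reshape(n, self.hout, self.wout, c, self.k, self.k)
        d = d.transpose(0, 3, 1, 2, 4, 5)
        p, s = self.pad, self.stride
        hp, wp = self.xshape[2] + 2 * p, self.xshape[3] + 2 * p
        dxp = np.zeros((n, c, hp, wp))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * self.hout : s, j : j + s * self.wout : s] += d[
                    :, :, :, :, i, j
                ]
        return dxp[:, :, p : hp - p, p : wp - p]


class Linear(Layer):
    def __init__(self, nin, nout, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = rng.standard_normal((nout, nin)) * np.sqrt(2.0 / nin)
        self.b = np.zeros(nout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self), ("b", self)]

    def forward(self, x):
        self.x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW = dy.T @ self.x
        self.db = dy.sum(axis=0)
        return dy @ self.W


class ReLU(Layer):
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dy):
        return dy * self.mask


class AvgPool2(Layer):
    """2x2 average pooling. Averaging rectified feature maps yields local
    texture-energy descriptors that are insensitive to phase, which matters
    when clusters should encode texture scale rather than pattern position."""

    def forward(self, x):
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        return dy.repeat(2, axis=2).repeat(2, axis=3) / 4.0


class GlobalAvgPool(Layer):
    """Spatial mean per channel: (N,C,H,W) -> (N,C). Makes the latent a
    translation-invariant texture-energy descriptor."""

    def forward(self, x):
        self.xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self.xshape
        return np.broadcast_to(dy[:, :, None, None], self.xshape) / (h * w)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling (the 'upsampling operation' of the decoder)."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps))
    dlogits = (p - targets) / logits.size
    return loss, dlogits


def mse(pred, target):
    """Mean squared error; returns (loss, dpred)."""
    diff = pred - target
    loss = np.mean(diff**2)
    return loss, 2.0 * diff / diff.size


class Adam:
    """Adam over the (W, b) slots of a list of layers."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = []
        for layer in layers:
            for name, owner in layer.params():
                val = getattr(owner, name)
                self.slots.append(
                    {
                        "owner": owner,
                        "name": name,
                        "m": np.zeros_like(val),
                        "v": np.zeros_like(val),
                    }
                )
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        for s in self.slots:
            g = getattr(s["owner"], "d" + s["name"])
            s["m"] = self.b1 * s["m"] + (1 - self.b1) * g
            s["v"] = self.b2 * s["v"] + (1 - self.b2) * g * g
            mhat = s["m"] / (1 - self.b1**self.t)
            vhat = s["v"] / (1 - self.b2**self.t)
            val = getattr(s["owner"], s["name"])
            val -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
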