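"""Minimal CPU neural-network core: strided convolutions with analytic
backprop, bilinear resampling, and Adam.

Sized for the small reference backbone (64x64 RGB -> 8x8x32 feature map);
everything is plain NumPy so training is bit-reproducible on a single thread.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ReLU",
    "TinyConvNet",
    "Adam",
    "bilinear_resize",
    "bilinear_resize_backward",
    "sigmoid",
    "softmax",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable split form
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Conv2d:
    """2-D convolution (cross-correlation), NCHW layout."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * ksize * ksize))  # He init for ReLU nets
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, ksize, ksize))
        self.b = np.zeros(c_out)
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._win = None
        self._xshape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.ksize, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._win = win
        self._xshape = x.shape
        y = np.einsum("bchwij,ocij->bohw", win, self.W, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.ksize, self.stride, self.pad
        self.dW = np.einsum("bchwij,bohw->ocij", self._win, dy, optimize=True)
        self.db = dy.sum(axis=(0, 2, 3))
        B, C, H, W = self._xshape
        ho, wo = dy.shape[2], dy.shape[3]
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += np.einsum(
                    "bohw,oc->bchw", dy, self.W[:, :, i, j], optimize=True)
        return dxp[:, :, p:p + H, p:p + W]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)

    def params(self):
        return []

    def grads(self):
        return []


class TinyConvNet:
    """Reference feature extractor: three stride-2 conv+ReLU blocks.

    64x64x3 input -> 8x8x32 feature map (NCHW internally). The final ReLU
    keeps the feature map nonnegative, so a ReLU-weighted channel sum (the
    CAM) is nonnegative too.
    """

    CHANNELS = (16, 32, 32)

    def __init__(self, in_channels: int = 3, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.layers = []
        c_prev = in_channels
        for c in self.CHANNELS:
            self.layers.append(Conv2d(c_prev, c, ksize=3, stride=2, pad=1, rng=rng))
            self.layers.append(ReLU())
            c_prev = c
        self.out_channels = c_prev

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, d_fmap: np.ndarray) -> None:
        d = d_fmap
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.grads())
        return out

    def copy(self) -> "TinyConvNet":
        other = TinyConvNet.__new__(TinyConvNet)
        other.layers = []
        for layer in self.layers:
            if isinstance(layer, Conv2d):
                dup = Conv2d.__new__(Conv2d)
                dup.W = layer.W.copy()
                dup.b = layer.b.copy()
                dup.ksize, dup.stride, dup.pad = layer.ksize, layer.stride, layer.pad
                dup.dW = np.zeros_like(dup.W)
                dup.db = np.zeros_like(dup.b)
                dup._win = None
                dup._xshape = None
                other.layers.append(dup)
            else:
                other.layers.append(ReLU())
        other.out_channels = self.out_channels
        return other


def _lin_coeffs(n_in: int, n_out: int):
    """Source rows/weights for 1-D linear resampling, align_corners=False."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.floor(src).astype(int)
    frac = src - i0
    lo = np.clip(i0, 0, n_in - 1)
    hi = np.clip(i0 + 1, 0, n_in - 1)
    return lo, hi, frac


def bilinear_resize(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize over the last two axes (align_corners=False)."""
    h, w = x.shape[-2], x.shape[-1]
    r0, r1, fy = _lin_coeffs(h, out_h)
    c0, c1, fx = _lin_coeffs(w, out_w)
    top = x[..., r0, :] * (1.0 - fy)[:, None] + x[..., r1, :] * fy[:, None]
    return top[..., :, c0] * (1.0 - fx) + top[..., :, c1] * fx


def bilinear_resize_backward(dy: np.ndarray, in_h: int, in_w: int) -> np.ndarray:
    """Adjoint of :func:`bilinear_resize` for (B, H, W) gradients."""
    B, oh, ow = dy.shape
    r0, r1, fy = _lin_coeffs(in_h, oh)
    c0, c1, fx = _lin_coeffs(in_w, ow)
    dtop = np.zeros((B, oh, in_w))
    np.add.at(dtop, (slice(None), slice(None), c0), dy * (1.0 - fx))
    np.add.at(dtop, (slice(None), slice(None), c1), dy * fx)
    dx = np.zeros((B, in_h, in_w))
    np.add.at(dx, (slice(None), r0, slice(None)), dtop * (1.0 - fy)[:, None])
    np.add.at(dx, (slice(None), r1, slice(None)), dtop * fy[:, None])
    return dx


class Adam:
    """Adam with bias correction; updates parameter arrays in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float | None = None) -> None:
        if lr is None:
            lr = self.lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
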