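"""Layers with explicit forward/backward passes on NCHW arrays.

Convolutions are bias-free (the backbone always normalizes after them) and are
evaluated through im2col + matmul so the heavy lifting stays in BLAS. Batch
normalization carries running statistics alongside its learned scale/shift,
so a layer with C channels accounts for 4*C parameters in total, matching the
trainable + non-trainable split that deep-learning frameworks report.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base layer: subclasses implement forward/backward and list params."""

    def params(self) -> list[Param]:
        return []

    def state_arrays(self) -> list[np.ndarray]:
        """Non-learned tracked arrays (running statistics)."""
        return []

    def n_params(self, include_state: bool = True) -> int:
        n = sum(p.size for p in self.params())
        if include_state:
            n += sum(a.size for a in self.state_arrays())
        return n

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Return (cols, out_h, out_w) with cols shaped (N, C*k*k, OH*OW).

    Channel-first column layout: the innermost copied axis runs along the
    image row, so building the columns is a sequence of contiguous row
    copies instead of a gather, which keeps im2col memory-bound-fast.
    """
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    win = sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, :: stride, :: stride][:, :, :oh, :ow]
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))
    return cols.reshape(n, c * k * k, oh * ow), oh, ow


class Conv2d(Layer):
    """Bias-free 2-d convolution.

    ``first=True`` marks the network's input layer, whose input gradient is
    never needed and is skipped for speed.
    """

    def __init__(self, c_in, c_out, kernel, stride=1, pad=0, *, first=False,
                 rng=None, dtype=np.float32):
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.first = first
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(c_out, c_in, kernel, kernel))
        self.weight = Param(w.astype(dtype), "conv_w")
        self._cache = None

    def params(self):
        return [self.weight]

    def forward(self, x, training=False):
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x.shape
        if k == 1 and s == 1 and p == 0:
            xm = x.reshape(n, c, h * w)
            self._cache = (xm, (h, w))
            wm = self.weight.data.reshape(self.c_out, self.c_in)
            return np.matmul(wm[None], xm).reshape(n, self.c_out, h, w)
        cols, oh, ow = _im2col(x, k, s, p)
        self._cache = (cols, (h, w))
        wm = self.weight.data.reshape(self.c_out, -1)
        return np.matmul(wm[None], cols).reshape(n, self.c_out, oh, ow)

    def backward(self, dy):
        cols, (h, w) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        n, f, oh, ow = dy.shape
        dym = dy.reshape(n, f, oh * ow)
        # per-sample GEMM with implicit B-transpose avoids copying `cols`
        dw = dym[0] @ cols[0].T
        for i in range(1, n):
            dw += dym[i] @ cols[i].T
        self.weight.grad += dw.reshape(self.weight.data.shape)
        self._cache = None
        if self.first:
            return None
        if k == 1 and s == 1 and p == 0:
            wm = self.weight.data.reshape(f, self.c_in)
            return np.matmul(wm.T[None], dym).reshape(n, self.c_in, h, w)
        return self._input_grad(dy, (h, w))

    def _input_grad(self, dy, in_hw):
        """Transposed-convolution input gradient, via the same im2col path."""
        k, s, p = self.kernel, self.stride, self.pad
        n, f, oh, ow = dy.shape
        h, w = in_hw
        hp, wp = h + 2 * p, w + 2 * p
        hd, wd = (oh - 1) * s + 1, (ow - 1) * s + 1
        if s == 1 and hd == h + 2 * p - k + 1 and wd == w + 2 * p - k + 1:
            dyd = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        else:
            dyd = np.zeros((n, f, hd + 2 * (k - 1), wd + 2 * (k - 1)),
                           dy.dtype)
            dyd[:, :, k - 1:k - 1 + hd:s, k - 1:k - 1 + wd:s] = dy
        w_rot = self.weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        w_rot = np.ascontiguousarray(w_rot).reshape(self.c_in, -1)
        cols, ch, cw = _im2col(dyd, k, 1, 0)
        dxp_part = np.matmul(w_rot[None], cols).reshape(n, self.c_in, ch, cw)
        if ch == hp and cw == wp:
            dxp = dxp_part
        else:
            dxp = np.zeros((n, self.c_in, hp, wp), dy.dtype)
            dxp[:, :, :ch, :cw] = dxp_part
        if p:
            return np.ascontiguousarray(dxp[:, :, p:p + h, p:p + w])
        return dxp


class BatchNorm2d(Layer):
    """Batch normalization over (N, H, W) per channel, with running stats."""

    def __init__(self, channels, momentum=0.9, eps=1e-5, dtype=np.float32):
        self.channels = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(np.ones(channels, dtype), "bn_gamma")
        self.beta = Param(np.zeros(channels, dtype), "bn_beta")
        self.running_mean = np.zeros(channels, dtype)
        self.running_var = np.ones(channels, dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean[:] = m * self.running_mean + (1 - m) * mean
            self.running_var[:] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * invstd[:, None, None]
        if training:
            self._cache = (xhat, invstd)
        g, b = self.gamma.data, self.beta.data
        return xhat * g[:, None, None] + b[:, None, None]

    def backward(self, dy):
        xhat, invstd = self._cache
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        axes = (0, 2, 3)
        dg = (dy * xhat).sum(axis=axes)
        db = dy.sum(axis=axes)
        self.gamma.grad += dg.astype(self.gamma.grad.dtype)
        self.beta.grad += db.astype(self.beta.grad.dtype)
        g = self.gamma.data
        dxhat = dy * g[:, None, None]
        dx = (invstd[:, None, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=axes)[:, None, None]
            - xhat * (dxhat * xhat).sum(axis=axes)[:, None, None]
        )
        return dx.astype(dy.dtype)


class BatchNorm1d(Layer):
    """Batch normalization over axis 0 of an (N, F) matrix."""

    def __init__(self, features, momentum=0.9, eps=1e-5, dtype=np.float32):
        self.features = features
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(np.ones(features, dtype), "bn1d_gamma")
        self.beta = Param(np.zeros(features, dtype), "bn1d_beta")
        self.running_mean = np.zeros(features, dtype)
        self.running_var = np.ones(features, dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.running_mean[:] = m * self.running_mean + (1 - m) * mean
            self.running_var[:] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if training:
            self._cache = (xhat, invstd)
        return xhat * self.gamma.data + self.beta.data

    def backward(self, dy):
        xhat, invstd = self._cache
        n = dy.shape[0]
        self.gamma.grad += (dy * xhat).sum(axis=0).astype(self.gamma.grad.dtype)
        self.beta.grad += dy.sum(axis=0).astype(self.beta.grad.dtype)
        dxhat = dy * self.gamma.data
        dx = (invstd / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        return dx.astype(dy.dtype)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    """Max pooling with (possibly overlapping) windows; -inf padding."""

    def __init__(self, kernel=3, stride=2, pad=1):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x, training=False):
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        hp, wp = h + 2 * p, w + 2 * p
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        win = win[:, :, :oh, :ow].reshape(n, c, oh, ow, k * k)
        arg = win.argmax(axis=-1)
        y = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, (n, c, h, w, hp, wp, oh, ow))
        return np.ascontiguousarray(y)

    def backward(self, dy):
        arg, (n, c, h, w, hp, wp, oh, ow) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        di, dj = np.divmod(arg, k)
        ii = di + np.arange(oh)[None, None, :, None] * s
        jj = dj + np.arange(ow)[None, None, None, :] * s
        flat = (ii * wp + jj).reshape(n * c, oh * ow)
        dxp = np.zeros((n * c, hp * wp), dy.dtype)
        rows = np.repeat(np.arange(n * c), oh * ow)
        np.add.at(dxp, (rows, flat.ravel()), dy.reshape(n * c, -1).ravel())
        dxp = dxp.reshape(n, c, hp, wp)
        if p:
            dxp = dxp[:, :, p:p + h, p:p + w]
        return np.ascontiguousarray(dxp)


class AvgPool2d(Layer):
    """Non-overlapping 2x2 stride-2 average pooling; odd edges dropped."""

    def __init__(self, kernel=2, stride=2):
        assert kernel == stride, "only non-overlapping average pooling"
        self.kernel = kernel
        self._shape = None

    def forward(self, x, training=False):
        k = self.kernel
        n, c, h, w = x.shape
        oh, ow = max(h // k, 1), max(w // k, 1)
        kh = min(k, h)
        kw = min(k, w)
        self._shape = (n, c, h, w, oh, ow, kh, kw)
        xt = x[:, :, :oh * kh, :ow * kw]
        return xt.reshape(n, c, oh, kh, ow, kw).mean(axis=(3, 5))

    def backward(self, dy):
        n, c, h, w, oh, ow, kh, kw = self._shape
        dx = np.zeros((n, c, h, w), dy.dtype)
        up = np.repeat(np.repeat(dy, kh, axis=2), kw, axis=3) / (kh * kw)
        dx[:, :, :oh * kh, :ow * kw] = up
        return dx


class GlobalAvgPool(Layer):
    """Collapse each feature map to its spatial mean: (N,C,H,W) -> (N,C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               (n, c, h, w)).astype(dy.dtype).copy()


class Dense(Layer):
    def __init__(self, n_in, n_out, *, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (n_in + n_out))
        w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.weight = Param(w.astype(dtype), "dense_w")
        self.bias = Param(np.zeros(n_out, dtype), "dense_b")
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, dy):
        self.weight.grad += (self._x.T @ dy).astype(self.weight.grad.dtype)
        self.bias.grad += dy.sum(axis=0).astype(self.bias.grad.dtype)
        return dy @ self.weight.data.T


class Dropout(Layer):
    """Inverted dropout; identity when rate is 0 or at inference."""

    def __init__(self, rate, rng=None):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1): {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Return (mean loss, probabilities, dlogits) for one-hot targets."""
    probs = softmax(logits)
    eps = np.finfo(probs.dtype).tiny
    loss = -(onehot * np.log(probs + eps)).sum(axis=1).mean()
    dlogits = (probs - onehot) / logits.shape[0]
    return float(loss), probs, dlogits.astype(logits.dtype)
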