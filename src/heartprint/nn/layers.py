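"""Minimal NumPy layers with explicit forward/backward passes.

Data layout is NHWC float32 (channels last), chosen so im2col window
gathers copy contiguous ``kw*c`` chunks instead of single elements.
Each layer caches what its backward pass needs; ``params()`` /
``grads()`` expose flat lists for the optimizer.  Convolution reduces to
a single GEMM over im2col columns.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "GlobalMaxPool",
           "Dense", "softmax", "cross_entropy_grad"]


def _window_view(x: np.ndarray, kh: int, kw: int, stride: int):
    """Strided view (N, out_h, out_w, kh, kw, C) of an NHWC array."""
    n, h, w, c = x.shape
    out_h = (h - kh) // stride + 1
    out_w = (w - kw) // stride + 1
    s = x.strides
    return np.lib.stride_tricks.as_strided(
        x, shape=(n, out_h, out_w, kh, kw, c),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]),
        writeable=False), out_h, out_w


def _pad(x: np.ndarray, pad: int, value: float = 0.0) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)),
                  constant_values=value)


def _col2im(gcols: np.ndarray, x_shape, kh: int, kw: int, stride: int,
            pad: int) -> np.ndarray:
    """Scatter-add (N, oh, ow, kh, kw, C) gradients back onto the input."""
    n, h, w, c = x_shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    xp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=gcols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, i:i + stride * oh:stride, j:j + stride * ow:stride, :] \
                += gcols[:, :, :, i, j, :]
    if pad:
        return xp[:, pad:-pad, pad:-pad, :]
    return xp


class Conv2d:
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        # He initialization for ReLU networks
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in),
                            (kernel, kernel, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.stride, self.pad, self.kernel = stride, pad, kernel
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        xp = _pad(x, self.pad)
        self._x_shape = x.shape
        if self.stride == 1:
            # shift-and-GEMM: no im2col gather; one GEMM per kernel tap
            n, hp, wp, c = xp.shape
            oh, ow = hp - k + 1, wp - k + 1
            self._xp = xp
            out = np.broadcast_to(self.b, (n, oh, ow, self.w.shape[3])).copy()
            for i in range(k):
                for j in range(k):
                    out += xp[:, i:i + oh, j:j + ow, :] @ self.w[i, j]
            self._oh, self._ow = oh, ow
            return out
        win, oh, ow = _window_view(xp, k, k, self.stride)
        cols = win.reshape(-1, k * k * x.shape[3])  # copy, chunked
        self._cols = cols
        self._oh, self._ow = oh, ow
        out = cols @ self.w.reshape(-1, self.w.shape[3]) + self.b
        return out.reshape(len(x), oh, ow, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oh, ow, c_out = grad.shape
        k = self.kernel
        g2 = grad.reshape(-1, c_out)
        self.db = g2.sum(axis=0)
        if self.stride == 1:
            xp = self._xp
            gx = np.zeros_like(xp)
            dw = np.empty_like(self.w)
            gmat = grad.reshape(-1, c_out)
            for i in range(k):
                for j in range(k):
                    patch = xp[:, i:i + oh, j:j + ow, :].reshape(-1, xp.shape[3])
                    dw[i, j] = patch.T @ gmat
                    gx[:, i:i + oh, j:j + ow, :] += grad @ self.w[i, j].T
            self.dw = dw
            if self.pad:
                return gx[:, self.pad:-self.pad, self.pad:-self.pad, :]
            return gx
        self.dw = (self._cols.T @ g2).reshape(self.w.shape)
        gcols = (g2 @ self.w.reshape(-1, c_out).T).reshape(
            n, oh, ow, k, k, self._x_shape[3])
        return _col2im(gcols, self._x_shape, k, k, self.stride, self.pad)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def n_parameters(self) -> int:
        return self.w.size + self.b.size


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(self.gamma.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(self.gamma.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._xhat, self._inv = xhat, inv
        return self.gamma * xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.dgamma = (grad * xhat).sum(axis=(0, 1, 2))
        self.dbeta = grad.sum(axis=(0, 1, 2))
        gxhat = grad * self.gamma
        term = (gxhat
                - gxhat.mean(axis=(0, 1, 2), keepdims=True)
                - xhat * (gxhat * xhat).mean(axis=(0, 1, 2), keepdims=True))
        return term * inv

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def n_parameters(self) -> int:
        return self.gamma.size + self.beta.size


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def params(self):
        return []

    def grads(self):
        return []

    def n_parameters(self) -> int:
        return 0


class MaxPool2d:
    def __init__(self, kernel: int = 2, stride: int = 2, pad: int = 0):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        xp = _pad(x, self.pad, value=-np.inf)
        win, oh, ow = _window_view(xp, k, k, self.stride)
        n, c = x.shape[0], x.shape[3]
        cols = win.reshape(n, oh, ow, k * k, c)
        self._argmax = cols.argmax(axis=3)
        self._x_shape, self._oh, self._ow = x.shape, oh, ow
        return cols.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oh, ow, c = grad.shape
        k = self.kernel
        gcols = np.zeros((n, oh, ow, k * k, c), dtype=grad.dtype)
        np.put_along_axis(gcols, self._argmax[:, :, :, None, :],
                          grad[:, :, :, None, :], axis=3)
        gcols = gcols.reshape(n, oh, ow, k, k, c)
        return _col2im(gcols, self._x_shape, k, k, self.stride, self.pad)

    def params(self):
        return []

    def grads(self):
        return []

    def n_parameters(self) -> int:
        return 0


class GlobalMaxPool:
    """Max over the spatial dimensions: (N,H,W,C) -> (N,C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        flat = x.reshape(n, h * w, c)
        self._argmax = flat.argmax(axis=1)
        self._x_shape = x.shape
        return flat.max(axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        out = np.zeros((n, h * w, c), dtype=grad.dtype)
        np.put_along_axis(out, self._argmax[:, None, :], grad[:, None, :],
                          axis=1)
        return out.reshape(self._x_shape)

    def params(self):
        return []

    def grads(self):
        return []

    def n_parameters(self) -> int:
        return 0


class Dense:
    def __init__(self, f_in: int, f_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0, np.sqrt(2.0 / f_in), (f_in, f_out)).astype(np.float32)
        self.b = np.zeros(f_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def n_parameters(self) -> int:
        return self.w.size + self.b.size


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(probs: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = len(targets)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), targets] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n
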