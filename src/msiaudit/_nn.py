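"""Minimal NumPy neural-network layers for the patch classifier.

Implements exactly what the dense-connectivity classifier needs: 2-d
convolution via im2col with an analytic backward pass, ReLU, average
pooling, a fully-connected head, softmax cross-entropy, and Adam.  All
parameters and activations are float32; loss accumulation is float64.
Every backward pass is checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Conv2d:
    """k x k convolution (NCHW layout) with stride and symmetric zero padding."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, name: str):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.name = name
        fan_in = cin * k * k
        # He initialization for ReLU networks
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self):
        return [(f"{self.name}.W", self.W, self.dW), (f"{self.name}.b", self.b, self.db)]

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.pad - self.k) // self.stride + 1,
                (w + 2 * self.pad - self.k) // self.stride + 1)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        assert c == self.cin, (c, self.cin)
        p, k, s = self.pad, self.k, self.stride
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh, ow = self.out_hw(h, w)
        # (n, c, oh, ow, k, k) strided view, subsampled by stride
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s, :, :]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        cols = np.ascontiguousarray(cols)
        y = cols @ self.W.T + self.b
        if cache:
            self._cols = cols
            self._in_shape = (n, c, h, w)
        return y.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        p, k, s = self.pad, self.k, self.stride
        oh, ow = self.out_hw(h, w)
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.cout)
        self.dW[...] = (dyf.T @ self._cols).astype(DTYPE)
        self.db[...] = dyf.sum(axis=0).astype(DTYPE)
        dcols = (dyf @ self.W).reshape(n, oh, ow, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        # scatter the column gradient back with 9 (k*k) strided slice-adds
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + s * oh:s, dj:dj + s * ow:s] += \
                    dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self._cols = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if cache:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = dy * self._mask
        self._mask = None
        return g


class AvgPool2d:
    """2 x 2 average pooling, stride 2; odd trailing rows/cols are dropped."""

    def __init__(self):
        self._in_shape = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = h // 2, w // 2
        if cache:
            self._in_shape = x.shape
        return x[:, :, :oh * 2, :ow * 2].reshape(n, c, oh, 2, ow, 2).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        oh, ow = h // 2, w // 2
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        up = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * 0.25
        dx[:, :, :oh * 2, :ow * 2] = up
        return dx


class GlobalAvgPool:
    def __init__(self):
        self._in_shape = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        if cache:
            self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._in_shape).astype(DTYPE)


class Dense:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str):
        self.W = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.name = name
        self._x = None

    def params(self):
        return [(f"{self.name}.W", self.W, self.dW), (f"{self.name}.b", self.b, self.db)]

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        if cache:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = (dy.T @ self._x).astype(DTYPE)
        self.db[...] = dy.sum(axis=0).astype(DTYPE)
        dx = dy @ self.W
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z.astype(np.float64))
    return (e / e.sum(axis=1, keepdims=True))


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(probs[np.arange(labels.size), labels], 1e-12, None)
    return float(-np.mean(np.log(p)))


def softmax_ce_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d(mean CE)/dlogits for softmax + cross-entropy."""
    g = probs.copy()
    g[np.arange(labels.size), labels] -= 1.0
    return (g / labels.size).astype(DTYPE)


class Adam:
    """Adam with decoupled-from-loss L2 term added to the gradient
    (equivalent to the conventional ``weight_decay`` argument)."""

    def __init__(self, params, lr: float = 1e-3, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params  # list of (name, value, grad)
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(v) for _, v, _ in params]
        self.v = [np.zeros_like(v) for _, v, _ in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (name, val, grad) in enumerate(self.params):
            g = grad
            if self.wd and not name.endswith(".b"):
                g = g + self.wd * val
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            val -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
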