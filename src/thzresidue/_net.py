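"""Minimal NumPy layer library backing the 1-D CNN classifier.

Each layer caches what its backward pass needs; parameters and their
gradients live on the layer objects and are collected by the optimizer.
Shapes follow the (batch, channels, length) convention for convolutional
stages and (batch, features) for dense stages.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "BatchNorm",
    "Dense",
    "Dropout",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    params: tuple = ()
    grads: tuple = ()

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Valid cross-correlation, stride 1, kernel size ``k``."""

    def __init__(self, in_channels: int, out_channels: int, k: int, rng):
        scale = np.sqrt(2.0 / (in_channels * k))  # He init for ReLU stages
        self.W = rng.normal(0.0, scale, size=(out_channels, in_channels, k))
        self.b = np.zeros(out_channels)
        self.k = k

    @property
    def params(self):
        return (self.W, self.b)

    @property
    def grads(self):
        return (self.dW, self.db)

    def forward(self, x, train: bool):
        n, c, length = x.shape
        out_len = length - self.k + 1
        if out_len < 1:
            raise ValueError(
                f"input length {length} too short for kernel size {self.k}"
            )
        win = sliding_window_view(x, self.k, axis=2)  # (n, c, out_len, k)
        self._win2 = win.transpose(0, 2, 1, 3).reshape(n * out_len, c * self.k)
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = self._win2 @ wmat.T + self.b
        self._shape = (n, c, length, out_len)
        return out.reshape(n, out_len, -1).transpose(0, 2, 1)

    def backward(self, dout):
        n, c, length, out_len = self._shape
        dout2 = dout.transpose(0, 2, 1).reshape(n * out_len, -1)
        wmat = self.W.reshape(self.W.shape[0], -1)
        self.dW = (dout2.T @ self._win2).reshape(self.W.shape)
        self.db = dout2.sum(axis=0)
        dwin = (dout2 @ wmat).reshape(n, out_len, c, self.k)
        dx = np.zeros((n, c, length))
        for kk in range(self.k):
            dx[:, :, kk : kk + out_len] += dwin[:, :, :, kk].transpose(0, 2, 1)
        return dx


class ReLU(Layer):
    def forward(self, x, train: bool):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x, train: bool):
        n, c, length = x.shape
        out_len = length // self.k
        if out_len < 1:
            raise ValueError(f"input length {length} too short for pool {self.k}")
        xv = x[:, :, : out_len * self.k].reshape(n, c, out_len, self.k)
        self._argmax = xv.argmax(axis=3)
        self._shape = x.shape
        return xv.max(axis=3)

    def backward(self, dout):
        n, c, length = self._shape
        out_len = length // self.k
        dx = np.zeros((n, c, out_len, self.k))
        ii, jj, ll = np.ogrid[:n, :c, :out_len]
        dx[ii, jj, ll, self._argmax] = dout
        return np.concatenate(
            [dx.reshape(n, c, out_len * self.k),
             np.zeros((n, c, length - out_len * self.k))],
            axis=2,
        )


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial) axes.

    ``spatial=True`` normalizes (n, c, l) tensors per channel; otherwise
    (n, f) per feature.  Training uses batch statistics and updates running
    moments used at inference.
    """

    def __init__(self, n_channels: int, spatial: bool = False, momentum: float = 0.9):
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.spatial = spatial
        self.momentum = momentum
        self.run_mean = np.zeros(n_channels)
        self.run_var = np.ones(n_channels)
        self.eps = 1e-5

    @property
    def params(self):
        return (self.gamma, self.beta)

    @property
    def grads(self):
        return (self.dgamma, self.dbeta)

    def _axes(self):
        return (0, 2) if self.spatial else (0,)

    def _expand(self, v):
        return v[None, :, None] if self.spatial else v[None, :]

    def forward(self, x, train: bool):
        axes = self._axes()
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - self._expand(mean)) * self._expand(self._istd)
        return self._expand(self.gamma) * self._xhat + self._expand(self.beta)

    def backward(self, dout):
        axes = self._axes()
        m = np.prod([dout.shape[a] for a in axes])
        self.dgamma = (dout * self._xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        dxhat = dout * self._expand(self.gamma)
        dx = (
            dxhat
            - self._expand(dxhat.mean(axis=axes))
            - self._xhat * self._expand((dxhat * self._xhat).sum(axis=axes) / m)
        ) * self._expand(self._istd)
        return dx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def params(self):
        return (self.W, self.b)

    @property
    def grads(self):
        return (self.dW, self.db)

    def forward(self, x, train: bool):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(z: np.ndarray, onehot: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(z)
    n = len(z)
    loss = float(-(onehot * np.log(np.maximum(p, 1e-12))).sum() / n)
    return loss, (p - onehot) / n


class Adam:
    """Adaptive moment estimation over a list of parameter arrays."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.99, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
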