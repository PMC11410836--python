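"""Differentiable layers and the Adam optimizer (numpy, NCHW layout)."""

from __future__ import annotations

from typing import List

import numpy as np

Array = np.ndarray


def _im2col(x: Array, k: int) -> Array:
    """Unfold k x k 'same' patches: (N, C, H, W) -> (N, H*W, C*k*k)."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k) -> (N, H*W, C*k*k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
    return np.ascontiguousarray(cols)


class Layer:
    """Minimal layer protocol: forward caches, backward consumes."""

    params: List[Array] = []
    grads: List[Array] = []

    def forward(self, x: Array) -> Array:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: Array) -> Array:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k x k stride-1 'same' convolution with bias, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                 size=(c_out, fan_in))
        self.bias = np.zeros(c_out)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]
        self._cols: Array | None = None
        self._shape = None

    def forward(self, x: Array) -> Array:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        cols = _im2col(x, self.k)
        self._cols, self._shape = cols, (n, c, h, w)
        out = cols @ self.weight.T + self.bias
        return out.transpose(0, 2, 1).reshape(n, self.c_out, h, w)

    def backward(self, dout: Array) -> Array:
        n, c, h, w = self._shape
        dflat = dout.reshape(n, self.c_out, h * w).transpose(0, 2, 1)
        self.grads[0][...] = np.einsum("npo,npk->ok", dflat, self._cols,
                                       optimize=True)
        self.grads[1][...] = dflat.sum(axis=(0, 1))
        self._cols = None
        # dx = 'same' convolution of dout with the spatially flipped,
        # channel-transposed kernel
        wmat = self.weight.reshape(self.c_out, self.c_in, self.k, self.k)
        wflip = wmat[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, k, k)
        cols = _im2col(dout, self.k)
        dx = cols @ wflip.reshape(self.c_in, -1).T
        return dx.transpose(0, 2, 1).reshape(n, c, h, w)


class ReLU(Layer):
    def forward(self, x: Array) -> Array:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: Array) -> Array:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: Array) -> Array:
        # piecewise formulation avoids overflow for large negative inputs
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dout: Array) -> Array:
        return dout * self._out * (1.0 - self._out)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization with learnable scale and shift.

    Keeps feature magnitudes O(1) through the unnormalized trunk; without it
    the output head's pre-activations are hostage to the (growing) feature
    scale and the sigmoid saturates early in training.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: Array) -> Array:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout: Array) -> Array:
        xhat, inv = self._xhat, self._inv
        self.grads[0][...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        m = dxhat.mean(axis=(2, 3), keepdims=True)
        mx = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dxhat - m - xhat * mx)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (even spatial sizes only)."""

    def forward(self, x: Array) -> Array:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return flat.max(axis=-1)

    def backward(self, dout: Array) -> Array:
        n, c, h, w = self._shape
        onehot = np.eye(4, dtype=dout.dtype)[self._arg]  # (n,c,h/2,w/2,4)
        blocks = (dout[..., None] * onehot).reshape(n, c, h // 2, w // 2, 2, 2)
        return blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class UpsampleNearest2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: Array) -> Array:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: Array) -> Array:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: List[Array], grads: List[Array],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
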