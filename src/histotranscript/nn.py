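"""Minimal NumPy neural-network engine for feed-forward convolutional nets.

This module provides exactly what the feature-correlation analysis needs and
nothing more: ``Conv2d``/``ReLU``/``MaxPool2d``/``AvgPool2d``/``Linear``/
``Dropout``/``Flatten`` layers chained in a :class:`Sequential`, forward
passes with per-layer activation capture, reverse-mode gradients for
momentum-SGD training, and a *guided* backward mode in which ReLU units zero
the propagated gradient wherever the forward input was non-positive or the
incoming gradient negative (the guided-backpropagation saliency rule).

Layout is NCHW throughout; parameters are float32.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: a differentiable module with (possibly empty) parameters."""

    kind = "layer"

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


class Conv2d(Layer):
    kind = "conv"

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, pad=0, bias=True,
                 rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.dW] + ([self.db] if self.db is not None else [])

    def _wmat(self):
        # (out, k*k*in) with kernel-position-major, channel-minor column order
        return np.ascontiguousarray(
            self.W.transpose(0, 2, 3, 1).reshape(self.out_ch, -1))

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.pad
        n = x.shape[0]
        # channels-last internally: contiguous row copies instead of gathers
        xh = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
        if p:
            xh = np.pad(xh, ((0, 0), (p, p), (p, p), (0, 0)))
        _, h, w, c = xh.shape
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        cols = np.empty((n, ho, wo, k * k * c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                cols[..., (i * k + j) * c:(i * k + j + 1) * c] = \
                    xh[:, i:i + s * ho:s, j:j + s * wo:s, :]
        out = cols.reshape(-1, k * k * c) @ self._wmat().T
        if self.b is not None:
            out += self.b
        self._cache = (cols, xh.shape, (ho, wo))
        return np.ascontiguousarray(
            out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, grad, guided=False):
        cols, xpshape, (ho, wo) = self._cache
        n, hp, wp, c = xpshape
        k, s, p = self.kernel, self.stride, self.pad
        g = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        flat = cols.reshape(-1, k * k * c)
        dwmat = g.T @ flat  # (out, k*k*in)
        self.dW[...] = dwmat.reshape(self.out_ch, k, k, self.in_ch).transpose(0, 3, 1, 2)
        if self.b is not None:
            self.db[...] = g.sum(axis=0)
        dcols = (g @ self._wmat()).reshape(n, ho, wo, k * k * c)
        dxh = np.zeros(xpshape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxh[:, i:i + s * ho:s, j:j + s * wo:s, :] += \
                    dcols[..., (i * k + j) * c:(i * k + j + 1) * c]
        if p:
            dxh = dxh[:, p:-p, p:-p, :]
        return np.ascontiguousarray(dxh.transpose(0, 3, 1, 2))


class ReLU(Layer):
    kind = "relu"

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad, guided=False):
        g = np.where(self._mask, grad, 0)
        if guided:
            # guided backprop: additionally discard negative incoming gradients
            g = np.where(g > 0, g, 0)
        return g


class MaxPool2d(Layer):
    """Non-overlapping max pool; spatial dims must be divisible by the kernel."""

    kind = "maxpool"

    def __init__(self, kernel=2):
        self.kernel = kernel

    def forward(self, x, train=False):
        k = self.kernel
        n, c, h, w = x.shape
        if h % k or w % k:
            raise ValueError(f"maxpool kernel {k} does not divide input {h}x{w}")
        xr = x.reshape(n, c, h // k, k, w // k, k)
        out = xr.max(axis=(3, 5))
        self._argmask = xr == out[:, :, :, None, :, None]
        # resolve ties deterministically: keep only the first max per window
        flat = self._argmask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // k, w // k, k * k)
        first = np.argmax(flat, axis=-1)
        mask = np.zeros_like(flat, dtype=bool)
        np.put_along_axis(mask, first[..., None], True, axis=-1)
        self._argmask = mask.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        self._inshape = x.shape
        return out

    def backward(self, grad, guided=False):
        k = self.kernel
        n, c, h, w = self._inshape
        g = grad[:, :, :, None, :, None] * self._argmask
        return g.reshape(n, c, h, w)


class AvgPool2d(Layer):
    kind = "avgpool"

    def __init__(self, kernel=2):
        self.kernel = kernel

    def forward(self, x, train=False):
        k = self.kernel
        n, c, h, w = x.shape
        if h % k or w % k:
            raise ValueError(f"avgpool kernel {k} does not divide input {h}x{w}")
        self._inshape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, grad, guided=False):
        k = self.kernel
        n, c, h, w = self._inshape
        g = np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)
        return g


class Flatten(Layer):
    kind = "flatten"

    def forward(self, x, train=False):
        self._inshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, guided=False):
        return grad.reshape(self._inshape)


class Dropout(Layer):
    kind = "dropout"

    def __init__(self, p=0.5, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad, guided=False):
        if self._mask is None:
            return grad
        return grad * self._mask


class Linear(Layer):
    kind = "linear"

    def __init__(self, in_dim, out_dim, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_dim)
        self.W = (rng.standard_normal((out_dim, in_dim)) * scale).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad, guided=False):
        self.dW[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W


class Sequential:
    """An ordered chain of layers with activation capture and partial backprop."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, capture: set[int] | None = None):
        """Run the net; if ``capture`` is given, also return {index: activation}."""
        acts = {}
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if capture is not None and i in capture:
                acts[i] = x
        if capture is not None:
            return x, acts
        return x

    def backward(self, grad, guided=False, from_layer: int | None = None):
        """Backpropagate ``grad`` from the output (or from ``from_layer``'s
        output) down to the input; returns the input gradient."""
        start = len(self.layers) - 1 if from_layer is None else from_layer
        for layer in reversed(self.layers[: start + 1]):
            grad = layer.backward(grad, guided=guided)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    g = p
    g[np.arange(n), labels] -= 1.0
    return float(loss), g / n


class SGD:
    """Momentum SGD with decoupled-from-schedule weight decay."""

    def __init__(self, net: Sequential, lr: float, momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p) for p in net.params()]

    def step(self):
        for p, g, v in zip(self.net.params(), self.net.grads(), self._vel):
            g = g + self.weight_decay * p
            v *= self.momentum
            v += g
            p -= self.lr * v
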