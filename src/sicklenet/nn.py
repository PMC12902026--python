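"""Minimal NumPy neural-network layers with explicit backpropagation.

The embedding networks in this package are small convolutional models run on
CPU, so the layers are implemented directly on NumPy arrays (NCHW layout)
with hand-written forward and backward passes.  Each layer caches what its
backward pass needs during forward; ``Sequential`` chains layers, exposes
their parameters to the optimizer, and records the gradient flowing into
every layer's output — which is exactly what Grad-CAM needs.

Only what the package uses is implemented: 2-D convolution (im2col), ReLU,
2x2 max pooling, global average pooling, batch normalization, dropout, dense
layers and a sigmoid.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # n, c, ho, wo, k, k
    col = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(col), ho, wo


def _col2im(dcol: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d = dcol.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[
                :, :, :, :, i, j
            ]
    if pad == 0:
        return dxp
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2d(Layer):
    """k x k convolution, He-initialized, NCHW in and out."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k, k))
        self.w = Param(w)
        self.b = Param(np.zeros(out_ch))
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        col, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.w.value.reshape(self.out_ch, -1)
        out = col @ wmat.T + self.b.value
        out = out.reshape(x.shape[0], ho, wo, self.out_ch).transpose(0, 3, 1, 2)
        self._cache = (x.shape, col)
        return out

    def backward(self, grad):
        x_shape, col = self._cache
        n, _, _, _ = x_shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.w.grad += (g.T @ col).reshape(self.w.value.shape)
        self.b.grad += g.sum(axis=0)
        dcol = g @ self.w.value.reshape(self.out_ch, -1)
        return _col2im(dcol, x_shape, self.k, self.stride, self.pad)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2x2(Layer):
    def forward(self, x, train=False):
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "pooling expects even spatial dims"
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._in_shape
        dr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dr, self._idx[..., None], grad[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """NCHW -> NC by spatial mean."""

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class Dropout(Layer):
    def __init__(self, rate: float = 0.2, rng: np.random.Generator | None = None):
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class BatchNorm1d(Layer):
    """Per-feature batch normalization on (N, C) inputs with running stats."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        self._cache = (xhat, std, train, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, std, train, n = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        dxhat = grad * self.gamma.value
        if not train:
            return dxhat / std
        return (
            dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)
        ) / std


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1 - self._y)


class Sequential:
    """Named layer chain recording per-layer outputs and output-gradients."""

    def __init__(self, layers: Sequence[Tuple[str, Layer]]):
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.layers: List[Tuple[str, Layer]] = list(layers)
        self.outputs: Dict[str, np.ndarray] = {}
        self.grads_at: Dict[str, np.ndarray] = {}

    def params(self) -> List[Param]:
        return [p for _, layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def layer_names(self) -> List[str]:
        return [n for n, _ in self.layers]

    def index_of(self, name: str) -> int:
        for i, (n, _) in enumerate(self.layers):
            if n == name:
                return i
        raise KeyError(name)

    def forward(self, x: np.ndarray, train: bool = False,
                upto: Optional[str] = None) -> np.ndarray:
        self.outputs = {}
        for name, layer in self.layers:
            x = layer.forward(x, train=train)
            self.outputs[name] = x
            if name == upto:
                break
        return x

    def backward(self, grad: np.ndarray, from_layer: Optional[str] = None) -> np.ndarray:
        """Backpropagate; ``grad`` is d(scalar)/d(output of ``from_layer``).

        Stores, for every traversed layer, the gradient with respect to that
        layer's output in ``self.grads_at``.
        """
        start = len(self.layers) - 1 if from_layer is None else self.index_of(from_layer)
        self.grads_at = {}
        for name, layer in reversed(self.layers[: start + 1]):
            self.grads_at[name] = grad
            grad = layer.backward(grad)
        return grad

    def state_dict(self) -> Dict[str, np.ndarray]:
        state: Dict[str, np.ndarray] = {}
        for name, layer in self.layers:
            for i, p in enumerate(layer.params()):
                state[f"{name}.{i}"] = p.value
            if isinstance(layer, BatchNorm1d):
                state[f"{name}.running_mean"] = layer.running_mean
                state[f"{name}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            for i, p in enumerate(layer.params()):
                p.value[...] = state[f"{name}.{i}"]
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[f"{name}.running_mean"]
                layer.running_var[...] = state[f"{name}.running_var"]


class Adam:
    """Adam with per-parameter first/second moment estimates."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
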