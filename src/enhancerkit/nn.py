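"""Compact CNN engine on numpy with exact gradients.

Implements the small set of layers needed for 1D sequence models
(convolution with 'same' padding, batch normalization, ReLU, max-pooling,
dense, dropout) together with an Adam optimizer and MSE / binary
cross-entropy-with-logits losses.  Every layer implements an analytic
backward pass, and :meth:`Model.input_gradient` propagates the output
gradient all the way back to the one-hot input — the primitive on which
both the attribution and the gradient-based design modules rely.

All arrays are float32.  Inputs are shaped ``(n, length, channels)``.
"""

from __future__ import annotations

import json
from typing import Iterator

import numpy as np

__all__ = [
    "Conv1D",
    "BatchNorm",
    "ReLU",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "Dropout",
    "Model",
    "Adam",
    "mse_loss",
    "bce_with_logits_loss",
    "sigmoid",
]

_F32 = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base class; layers with parameters override ``params``."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _corr1d(x: np.ndarray, w: np.ndarray, pad_left: int, pad_right: int) -> np.ndarray:
    """Cross-correlate ``x`` (n, L, C) with ``w`` (k, C, F) after padding.

    Returns the output and the im2col matrix (rows ordered channel-major,
    i.e. (C, k) flattened) so the caller can reuse it for weight gradients.
    """
    k, cin, f = w.shape
    xp = np.pad(x, ((0, 0), (pad_left, pad_right), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (n, L', C, k) view
    n, lo = cols.shape[0], cols.shape[1]
    flat = cols.reshape(n * lo, cin * k)  # one internal contiguous copy
    out = flat @ w.transpose(1, 0, 2).reshape(cin * k, f)
    return out.reshape(n, lo, f), flat


class Conv1D(Layer):
    def __init__(self, in_channels: int, filters: int, kernel: int, rng: np.random.Generator):
        self.k = int(kernel)
        self.cin = int(in_channels)
        self.cout = int(filters)
        # 'same' padding for stride 1
        self.pl = (self.k - 1) // 2
        self.pr = self.k // 2
        std = np.sqrt(2.0 / (self.k * self.cin))
        self.W = rng.normal(0.0, std, size=(self.k, self.cin, self.cout)).astype(_F32)
        self.b = np.zeros(self.cout, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training):
        out, self._cols = _corr1d(x, self.W, self.pl, self.pr)
        self._n_l = (x.shape[0], x.shape[1])
        return out + self.b

    def backward(self, dout, need_dx: bool = True):
        n, L = self._n_l
        dflat = dout.reshape(n * L, self.cout)
        # cols are (C, k)-flattened; map weight gradient back to (k, C, F)
        self.dW[...] = (self._cols.T @ dflat).reshape(self.cin, self.k, self.cout).transpose(1, 0, 2)
        self.db[...] = dflat.sum(axis=0)
        self._cols = None
        if not need_dx:
            return None
        # gradient w.r.t. input: correlate dout with kernel flipped in position
        # and transposed in channels
        w_rev = self.W[::-1].transpose(0, 2, 1)  # (k, cout, cin)
        dx, _ = _corr1d(dout, np.ascontiguousarray(w_rev), self.k - 1 - self.pl, self.k - 1 - self.pr)
        return dx


class BatchNorm(Layer):
    """Batch normalization over the batch (and length, for 3-D inputs) axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=_F32)
        self.beta = np.zeros(channels, dtype=_F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def _axes(self, x):
        return (0, 1) if x.ndim == 3 else (0,)

    def forward(self, x, training):
        axes = self._axes(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean + (1 - self.momentum) * mean).astype(_F32)
            self.running_var = (self.momentum * self.running_var + (1 - self.momentum) * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        xhat = x - mean.astype(_F32)
        xhat *= inv
        if training:
            self._cache = (xhat, inv, axes)
        else:
            self._cache = None
            self._eval_inv = inv
        out = xhat * self.gamma
        out += self.beta
        return out

    def backward(self, dout):
        if self._cache is None:
            # eval-mode backward (used for input gradients): affine transform
            return dout * (self.gamma * self._eval_inv)
        xhat, inv, axes = self._cache
        m = np.prod([dout.shape[a] for a in axes])
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        dx = dout * _F32(m)
        dx -= self.dbeta
        xhat *= self.dgamma
        dx -= xhat
        dx *= self.gamma * inv / _F32(m)
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out


class MaxPool1D(Layer):
    """Non-overlapping max pooling; stride equals the pool size, remainder cropped."""

    def __init__(self, size: int):
        self.size = int(size)

    def forward(self, x, training):
        n, L, c = x.shape
        lo = L // self.size
        self._in_len = L
        xr = x[:, : lo * self.size].reshape(n, lo, self.size, c)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dout):
        n, lo, c = dout.shape
        dxr = np.zeros((n, lo, self.size, c), dtype=_F32)
        np.put_along_axis(dxr, self._arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros((n, self._in_len, c), dtype=_F32)
        dx[:, : lo * self.size] = dxr.reshape(n, lo * self.size, c)
        self._arg = None
        return dx


class AvgPool1D(Layer):
    """Non-overlapping average pooling; preserves motif counts within bins
    (a max pool reports presence only)."""

    def __init__(self, size: int):
        self.size = int(size)

    def forward(self, x, training):
        n, L, c = x.shape
        lo = L // self.size
        self._in_len = L
        return x[:, : lo * self.size].reshape(n, lo, self.size, c).mean(axis=2)

    def backward(self, dout):
        n, lo, c = dout.shape
        dx = np.zeros((n, self._in_len, c), dtype=_F32)
        spread = np.repeat(dout / _F32(self.size), self.size, axis=1)
        dx[:, : lo * self.size] = spread
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_in, n_out)).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_F32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out


class Model:
    """A sequential stack ending in a single linear output unit.

    ``head`` selects how :meth:`predict` post-processes the raw (pre-sigmoid)
    output: ``"linear"`` returns it unchanged, ``"sigmoid"`` squashes it.
    The raw output is always available (``output="logit"``), which keeps
    pre-sigmoid logits directly extractable for design-time optimization.
    """

    def __init__(self, layers: list[Layer], head: str = "linear"):
        if head not in ("linear", "sigmoid"):
            raise ValueError(f"unknown head {head!r}")
        self.layers = layers
        self.head = head

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=_F32)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out[:, 0]

    def backward(self, dout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        grad = np.asarray(dout, dtype=_F32)[:, None]
        for i, layer in zip(range(len(self.layers) - 1, -1, -1), reversed(self.layers)):
            if i == 0 and not need_input_grad and isinstance(layer, Conv1D):
                return layer.backward(grad, need_dx=False)
            grad = layer.backward(grad)
        return grad

    def predict(self, x: np.ndarray, output: str = "response", batch_size: int = 256) -> np.ndarray:
        """Evaluate the model; ``output`` is ``"response"`` or ``"logit"``."""
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i : i + batch_size], training=False))
        raw = np.concatenate(outs) if outs else np.zeros(0, dtype=_F32)
        if output == "logit" or self.head == "linear":
            return raw.astype(np.float64)
        return sigmoid(raw)

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(raw output)/d(input) for each sequence in the batch (eval mode)."""
        self.forward(x, training=False)
        return self.backward(np.ones(len(x), dtype=_F32))

    # -- parameter plumbing ------------------------------------------------
    def param_items(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        for i, layer in enumerate(self.layers):
            ps, gs = layer.params(), layer.grads()
            for name in ps:
                yield f"{i}.{name}", ps[name], gs[name]

    def get_weights(self) -> dict[str, np.ndarray]:
        w = {name: arr.copy() for name, arr, _ in self.param_items()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                w[f"{i}.running_mean"] = layer.running_mean.copy()
                w[f"{i}.running_var"] = layer.running_var.copy()
        return w

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, arr, _ in self.param_items():
            arr[...] = weights[name]
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = weights[f"{i}.running_mean"]
                layer.running_var[...] = weights[f"{i}.running_var"]

    def save(self, path) -> None:
        np.savez(path, **self.get_weights(), __head__=np.array(self.head))

    def load(self, path) -> None:
        with np.load(path, allow_pickle=False) as data:
            weights = {k: data[k] for k in data.files if k != "__head__"}
            self.head = str(data["__head__"])
        self.set_weights(weights)


class Adam:
    def __init__(self, model: Model, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(arr) for name, arr, _ in model.param_items()}
        self.v = {name: np.zeros_like(arr) for name, arr, _ in model.param_items()}

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for name, arr, grad in self.model.param_items():
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1 - self.beta1) * grad
            v *= self.beta2
            v += (1 - self.beta2) * grad * grad
            arr -= (self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)).astype(_F32)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 * diff / len(pred)).astype(_F32)


def bce_with_logits_loss(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    z, y = np.asarray(logits, dtype=np.float64), np.asarray(target, dtype=np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - y) / len(z)
    return float(loss.mean()), dz.astype(_F32)
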