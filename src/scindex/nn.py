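"""Minimal CPU neural-network layers used by the pain scorer.

Layers operate on float32 arrays in NHWC layout (batch, height, width,
channel).  Each layer exposes ``forward(x, train=..., rng=...)``,
``backward(dout)`` and two parallel dicts ``params`` / ``grads``.
Convolutions are evaluated as a single matrix product on an im2col
expansion, which keeps the whole training loop inside BLAS.

The only stochastic elements are parameter initialisation and dropout
masks; both draw from the ``numpy.random.Generator`` handed in by the
caller, so training is reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "Dropout",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]

_F32 = np.float32


class Layer:
    """Base layer: stateless unless a subclass declares parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """2D convolution, stride 1, 'same' output size.

    For an even kernel (the 2x2 case used here) the extra padding row and
    column go on the bottom/right, matching the TensorFlow 'SAME'
    convention, so the spatial size is preserved exactly.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 2, *, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = kernel * kernel * c_in
        # He initialisation, appropriate for the ReLU stages that follow
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.params = {"W": w.astype(_F32), "b": np.zeros(c_out, dtype=_F32)}

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k - 1
        return np.pad(x, ((0, 0), (0, p), (0, p), (0, 0)))

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        xp = self._pad(x)
        k = self.k
        cols = np.empty((n, h, w, k * k * c), dtype=x.dtype)
        idx = 0
        for di in range(k):
            for dj in range(k):
                cols[..., idx * c:(idx + 1) * c] = xp[:, di:di + h, dj:dj + w, :]
                idx += 1
        self._cols = cols.reshape(-1, k * k * c)
        self._xshape = x.shape
        out = self._cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout):
        n, h, w, c = self._xshape
        k = self.k
        d = dout.reshape(-1, self.c_out)
        self.grads["W"] = self._cols.T @ d
        self.grads["b"] = d.sum(axis=0)
        dcols = (d @ self.params["W"].T).reshape(n, h, w, k * k, c)
        p = k - 1
        dxp = np.zeros((n, h + p, w + p, c), dtype=dout.dtype)
        idx = 0
        for di in range(k):
            for dj in range(k):
                dxp[:, di:di + h, dj:dj + w, :] += dcols[:, :, :, idx, :]
                idx += 1
        self._cols = None
        return dxp[:, :h, :w, :]


class BatchNorm2D(Layer):
    """Per-channel batch normalisation over (batch, height, width).

    Training uses batch statistics and maintains exponential running
    moments; inference uses the running moments, so a trained scorer is
    deterministic.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(c, dtype=_F32), "beta": np.zeros(c, dtype=_F32)}
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            # single-pass moments: Var = E[x^2] - E[x]^2
            x2 = x.reshape(-1, x.shape[-1])
            mean = x2.mean(axis=0, dtype=np.float64)
            var = np.einsum('nc,nc->c', x2, x2, dtype=np.float64) \
                / x2.shape[0] - mean * mean
            var = np.maximum(var, 0.0)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(_F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(x.dtype)
        xhat = x - mean.astype(x.dtype)
        xhat /= self._std
        self._xhat = xhat
        self._train = train
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        m = float(np.prod([dout.shape[a] for a in axes]))
        xhat = self._xhat
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        if not self._train:
            return dxhat / self._std
        dx = (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) / self._std
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are
    dropped (floor semantics), which is what takes 31 -> 15."""

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, :h2 * 2, :w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        out = xr.max(axis=(2, 4))
        # ties share gradient equally, keeping backward an exact adjoint
        mask = (xr == out[:, :, None, :, None, :]).astype(x.dtype)
        mask /= mask.sum(axis=(2, 4), keepdims=True)
        self._mask = mask
        self._xshape = x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._xshape
        h2, w2 = h // 2, w // 2
        dxr = self._mask * dout[:, :, None, :, None, :]
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, :h2 * 2, :w2 * 2, :] = dxr.reshape(n, h2 * 2, w2 * 2, c)
        self._mask = None
        return dx


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = {"W": w.astype(_F32), "b": np.zeros(n_out, dtype=_F32)}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``labels`` are integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adaptive-moment optimiser over the parameter dicts of a layer stack."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
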