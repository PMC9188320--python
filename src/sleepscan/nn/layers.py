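"""Primitive layers with explicit forward/backward passes.

Every layer exposes ``params()`` returning ``{name: array}`` and
``grads()`` returning the matching gradient arrays; the Adam optimizer
updates them in place. Forward passes take ``train`` to switch dropout
and batch-normalization behaviour.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "ReLU", "Dropout", "BatchNorm1d", "Embedding", "LayerNorm", "Adam",
           "sigmoid", "bce_with_logits", "softmax_ce_with_logits"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-class binary cross-entropy against one-hot targets.

    Returns (loss, dloss/dz). Numerically stable log-sum form.
    """
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - t) / z.size
    return float(loss.mean()), dz


def softmax_ce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Categorical cross-entropy (optional alternative output head)."""
    zs = z - z.max(axis=1, keepdims=True)
    logp = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
    loss = -(t * logp).sum(axis=1).mean()
    dz = (np.exp(logp) - t) / z.shape[0]
    return float(loss), dz


class Dense:
    """Affine layer y = xW + b with He-scaled initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        flat_x = x.reshape(-1, x.shape[-1])
        flat_d = dout.reshape(-1, dout.shape[-1])
        self.dW += flat_x.T @ flat_d
        self.db += flat_d.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return {}

    def grads(self):
        return {}


class Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return {}

    def grads(self):
        return {}


class BatchNorm1d:
    """Batch normalization over the batch axis with running statistics."""

    def __init__(self, d: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(d)
        self.beta = np.zeros(d)
        self.dgamma = np.zeros(d)
        self.dbeta = np.zeros(d)
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, train)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        self.dgamma += (dout * xhat).sum(axis=0)
        self.dbeta += dout.sum(axis=0)
        dxhat = dout * self.gamma
        if not train:
            return dxhat * inv
        n = dout.shape[0]
        return (inv / n) * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}


class LayerNorm:
    """Per-position layer normalization (last axis)."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = np.ones(d)
        self.beta = np.zeros(d)
        self.dgamma = np.zeros(d)
        self.dbeta = np.zeros(d)
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = tuple(range(dout.ndim - 1))
        self.dgamma += (dout * xhat).sum(axis=axes)
        self.dbeta += dout.sum(axis=axes)
        dxhat = dout * self.gamma
        d = dout.shape[-1]
        return (inv / d) * (
            d * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}


class Embedding:
    """Token-id lookup table. Row 0 is the padding vector (kept at zero)."""

    def __init__(self, n_vocab: int, d: int, rng: np.random.Generator,
                 trainable: bool = True, weights: np.ndarray | None = None):
        if weights is not None:
            self.W = np.array(weights, dtype=float)
        else:
            self.W = rng.normal(0.0, 0.1, size=(n_vocab, d))
        self.W[0] = 0.0
        self.dW = np.zeros_like(self.W)
        self.trainable = trainable
        self._ids = None

    def forward(self, ids: np.ndarray, train: bool = False) -> np.ndarray:
        self._ids = ids
        return self.W[ids]

    def backward(self, dout: np.ndarray) -> None:
        if self.trainable:
            np.add.at(self.dW, self._ids, dout)
            self.dW[0] = 0.0  # padding stays zero

    def params(self):
        return {"W": self.W} if self.trainable else {}

    def grads(self):
        return {"W": self.dW} if self.trainable else {}


class Adam:
    """Adam over a list of (param, grad) array pairs; updates in place."""

    def __init__(self, pairs, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.pairs = list(pairs)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grads(self) -> None:
        for _, g in self.pairs:
            g[...] = 0.0
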