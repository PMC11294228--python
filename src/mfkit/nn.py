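"""Minimal feed-forward neural-network core (numpy, manual backprop).

Implements exactly the pieces the two regression heads of this package need:
dense layers, ReLU, inverted dropout, batch normalization, a sigmoid output
head and the Adam optimizer.  Training is fully deterministic given a seed.
Gradients are exercised against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "ReLU", "Dropout", "BatchNorm", "Sequential", "Adam",
           "sigmoid"]


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Dense:
    """Affine layer y = x W + b with He-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng):
        self.W = rng.normal(scale=np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train: bool):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, g):
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        yield self.W, self.dW
        yield self.b, self.db


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, train: bool):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, g):
        return g * self._mask

    def params(self):
        return iter(())


class Dropout:
    """Inverted dropout: active only in training mode."""

    def __init__(self, keep: float, rng):
        if not 0.0 < keep <= 1.0:
            raise ValueError("keep probability must lie in (0, 1]")
        self.keep = keep
        self.rng = rng
        self._mask = None

    def forward(self, x, train: bool):
        if not train or self.keep >= 1.0:
            return x
        self._mask = (self.rng.random(x.shape) < self.keep) / self.keep
        return x * self._mask

    def backward(self, g):
        return g * self._mask if self._mask is not None else g

    def params(self):
        return iter(())


class BatchNorm:
    """Batch normalization with running statistics for inference."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train: bool):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv)
        return self.gamma * xhat + self.beta

    def backward(self, g):
        xhat, inv = self._cache
        n = g.shape[0]
        self.dgamma = (g * xhat).sum(axis=0)
        self.dbeta = g.sum(axis=0)
        gx = self.gamma * g
        return inv / n * (n * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0))

    def params(self):
        yield self.gamma, self.dgamma
        yield self.beta, self.dbeta


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train: bool):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        for layer in self.layers:
            yield from layer.params()


class Adam:
    """Adam optimizer over (param, grad) pairs exposed by the model."""

    def __init__(self, param_source, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.source = param_source
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in param_source.params()]
        self.v = [np.zeros_like(p) for p, _ in param_source.params()]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (p, g) in enumerate(self.source.params()):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
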