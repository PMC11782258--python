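"""Minimal dense-layer machinery with hand-written backprop and Adam.

The point-cloud encoder and classification heads need only shared dense
layers (applied along the last axis of arbitrarily-batched arrays), ReLU,
inverted dropout, channel-wise max-pooling and softmax cross-entropy, so the
whole stack is a few hundred lines of numpy.  Parameters live in
:class:`Dense` objects; a network is a list of layers walked forward and
backward explicitly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLP", "Adam", "relu", "softmax", "cross_entropy_grad",
           "max_pool", "max_pool_backward"]


class Dense:
    """Affine layer ``y = x @ W + b`` applied along the last axis."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization (layers are ReLU-separated)
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        flat_x = x.reshape(-1, x.shape[-1])
        flat_d = dout.reshape(-1, dout.shape[-1])
        self.dW += flat_x.T @ flat_d
        self.db += flat_d.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def zero_grad(self):
        self.dW[...] = 0.0
        self.db[...] = 0.0


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class MLP:
    """Dense layers with ReLU between them (and optionally after the last)."""

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 final_relu: bool = True):
        self.layers = [Dense(widths[i], widths[i + 1], rng)
                       for i in range(len(widths) - 1)]
        self.final_relu = final_relu
        self._acts: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._acts = []
        n = len(self.layers)
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if i < n - 1 or self.final_relu:
                if train:
                    self._acts.append(x > 0)
                x = relu(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = len(self.layers)
        k = len(self._acts)
        for i in range(n - 1, -1, -1):
            if i < n - 1 or self.final_relu:
                k -= 1
                dout = dout * self._acts[k]
            dout = self.layers[i].backward(dout)
        return dout

    @property
    def dense_layers(self):
        return self.layers

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()


def max_pool(x: np.ndarray, axis: int):
    """Max over ``axis``; returns (pooled, argmax) for the backward pass."""
    arg = np.argmax(x, axis=axis)
    pooled = np.take_along_axis(x, np.expand_dims(arg, axis), axis=axis)
    return np.squeeze(pooled, axis=axis), arg


def max_pool_backward(dout: np.ndarray, arg: np.ndarray, axis: int,
                      size: int) -> np.ndarray:
    """Scatter ``dout`` back to the argmax positions along ``axis``."""
    shape = list(dout.shape)
    shape.insert(axis, size)
    dx = np.zeros(shape, dtype=dout.dtype)
    np.put_along_axis(dx, np.expand_dims(arg, axis),
                      np.expand_dims(dout, axis), axis=axis)
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam with decoupled-style L2 applied through the gradient."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.layers = list(layers)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for layer in self.layers for p in layer.params]
        self.v = [np.zeros_like(p) for layer in self.layers for p in layer.params]

    def step(self):
        self.t += 1
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                grad = g
                if self.weight_decay and p.ndim > 1:  # decay weights, not biases
                    grad = grad + self.weight_decay * p
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * grad
                self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * grad ** 2
                mhat = self.m[i] / (1 - self.beta1 ** self.t)
                vhat = self.v[i] / (1 - self.beta2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()


class SGD:
    """Plain SGD with momentum, matching the Adam interface."""

    def __init__(self, layers, lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.layers = list(layers)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.vel = [np.zeros_like(p) for layer in self.layers for p in layer.params]

    def step(self):
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                grad = g
                if self.weight_decay and p.ndim > 1:
                    grad = grad + self.weight_decay * p
                self.vel[i] = self.momentum * self.vel[i] - self.lr * grad
                p += self.vel[i]
                i += 1

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()
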