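"""Sequential network container, softmax cross-entropy loss and Adam."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean negative log-likelihood of integer targets ``y``."""
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


class Sequential:
    """Ordered layer stack mapping NHWC batches to class logits."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic inference (dropout off, batch-norm running stats)."""
        out = [
            softmax(self.forward(x[i: i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: "Adam") -> float:
        """One forward/backward/update pass; returns the batch loss."""
        logits = self.forward(x, train=True)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        grad = probs.copy()
        grad[np.arange(len(y)), y] -= 1.0
        grad /= len(y)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        optimizer.step()
        return loss

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        """Deep copies of all parameters and batch-norm running statistics."""
        state = [p.copy() for p in self.params]
        for layer in self._bn_layers():
            state.append(layer.running_mean.copy())
            state.append(layer.running_var.copy())
            state.append(np.array([layer.n_updates]))
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        params = self.params
        for p, s in zip(params, state[: len(params)]):
            p[...] = s
        rest = state[len(params):]
        for i, layer in enumerate(self._bn_layers()):
            layer.running_mean[...] = rest[3 * i]
            layer.running_var[...] = rest[3 * i + 1]
            layer.n_updates = int(rest[3 * i + 2][0])

    def _bn_layers(self):
        from .layers import BatchNorm, InceptionBlock

        found = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                found.append(layer)
            elif isinstance(layer, InceptionBlock):
                for br in layer.branches:
                    found.extend(l for l in br if isinstance(l, BatchNorm))
        return found

    def clone(self) -> "Sequential":
        return copy.deepcopy(self)


class Adam:
    """Adam optimizer over a network's flat parameter list."""

    def __init__(self, network: Sequential, learning_rate: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.network = network
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in network.params]
        self.v = [np.zeros_like(p) for p in network.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.network.params, self.network.grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
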