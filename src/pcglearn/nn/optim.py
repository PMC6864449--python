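"""First-order optimisers over a list of layers."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adagrad", "Adam", "make_optimizer", "clip_gradients"]


def clip_gradients(layers, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``
    (protects BPTT from occasional exploding gradients).  Returns the
    pre-clip norm."""
    total = 0.0
    for layer in layers:
        for g in layer.grads.values():
            total += float(np.sum(g.astype(np.float64) ** 2))
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for layer in layers:
            for k in layer.grads:
                layer.grads[k] = layer.grads[k] * scale
    return norm


class _Optimizer:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, layers) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(_Optimizer):
    def step(self, layers):
        for layer in layers:
            for k, g in layer.grads.items():
                layer.params[k] -= self.lr * g


class Adagrad(_Optimizer):
    def __init__(self, lr: float = 0.01, eps: float = 1e-8):
        super().__init__(lr)
        self.eps = eps
        self._acc: dict[tuple[int, str], np.ndarray] = {}

    def step(self, layers):
        for idx, layer in enumerate(layers):
            for k, g in layer.grads.items():
                key = (idx, k)
                if key not in self._acc:
                    self._acc[key] = np.zeros_like(g, dtype=np.float32)
                self._acc[key] += g * g
                layer.params[k] -= self.lr * g / (np.sqrt(self._acc[key]) + self.eps)


class Adam(_Optimizer):
    """Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self, layers):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for idx, layer in enumerate(layers):
            for k, g in layer.grads.items():
                key = (idx, k)
                if key not in self._m:
                    self._m[key] = np.zeros_like(g, dtype=np.float32)
                    self._v[key] = np.zeros_like(g, dtype=np.float32)
                m = self._m[key]
                v = self._v[key]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                layer.params[k] -= (
                    self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                )


_OPTIMIZERS = {"sgd": SGD, "adagrad": Adagrad, "adam": Adam}


def make_optimizer(name: str, lr: float) -> _Optimizer:
    try:
        cls = _OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}"
        ) from None
    return cls(lr)
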