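"""Network building blocks: linear maps, batch norm, dropout, stacks.

Layers follow the familiar module convention (``parameters()``, ``train()`` /
``eval()``); initialization is fan-in-scaled uniform from an explicit
``numpy.random.Generator`` so whole models are reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor

__all__ = [
    "Module",
    "Linear",
    "ReLU",
    "Dropout",
    "BatchNorm1d",
    "Softmax",
    "Sequential",
]


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _submodules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self) -> "Module":
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def __call__(self, x):
        return self.forward(as_tensor(x))


class Linear(Module):
    """Affine map with U(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_dim)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, size=(out_dim,)),
                           requires_grad=True)
        self.in_dim, self.out_dim = in_dim, out_dim

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(
                f"linear layer expects inputs of width {self.in_dim}, got {x.shape[-1]}"
            )
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    """Inverted dropout; masks are drawn from the layer's own generator."""

    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class BatchNorm1d(Module):
    """Per-feature normalization; batch statistics while training, running
    statistics in evaluation mode."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data[0]
            )
            xhat = (x - mu) / (var + self.eps) ** 0.5
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class Softmax(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.softmax(axis=-1)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
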