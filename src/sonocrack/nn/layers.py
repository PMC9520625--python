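"""Neural-network building blocks and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module", "Conv2d", "DepthwiseConv2d", "BatchNorm2d", "LayerNorm",
    "Linear", "Adam",
]


class Module:
    """Composable parameter container with train/eval state."""

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

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def named_state(self, prefix: str = ""):
        """Yield (name, holder) for every parameter and buffer.

        Holders are Tensors (parameters) or ndarrays (running stats);
        traversal order is deterministic, so a state saved from one
        instance loads into a freshly built identical architecture.
        """
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, np.ndarray):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_state(key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_state(f"{key}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        self.w = _he(rng, (kernel, kernel, cin, cout), kernel * kernel * cin)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        self.w = _he(rng, (kernel, kernel, channels), kernel * kernel)
        self.b = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv2d(x, self.w, self.b, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum,
                            self.eps)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.layernorm(x, self.gamma, self.beta, self.eps)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.w = _he(rng, (cin, cout), cin)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.w), self.b)


class Adam:
    """Adam with default moment coefficients (0.9, 0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
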