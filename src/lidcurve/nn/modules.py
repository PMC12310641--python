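"""Layer/module abstractions over the autograd core, plus Adam."""
from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter discovery by attribute walk, state (de)serialisation."""

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()
        for value in self.__dict__.values():
            yield from _params_of(value, seen)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        seen: set[int] = set()
        yield from _named_params_of(self, prefix, seen)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError("state dict keys do not match module parameters")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _params_of(value, seen: set[int]):
    if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
        seen.add(id(value))
        yield value
    elif isinstance(value, Module):
        for v in value.__dict__.values():
            yield from _params_of(v, seen)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _params_of(v, seen)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _params_of(v, seen)


def _named_params_of(obj, prefix: str, seen: set[int]):
    if isinstance(obj, Tensor):
        if obj.requires_grad and id(obj) not in seen:
            seen.add(id(obj))
            yield prefix, obj
    elif isinstance(obj, Module):
        for name, value in obj.__dict__.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from _named_params_of(value, sub, seen)
    elif isinstance(obj, (list, tuple)):
        for i, value in enumerate(obj):
            yield from _named_params_of(value, f"{prefix}.{i}", seen)
    elif isinstance(obj, dict):
        for key, value in obj.items():
            yield from _named_params_of(value, f"{prefix}.{key}", seen)


class Conv2d(Module):
    """3x3/1x1/7x7 convolution with He-normal init."""

    def __init__(self, cin: int, cout: int, k: int, *, stride: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = k // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(nout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.weight) + self.bias


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes with a
    learned channel-wise affine; batch-size independent."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = ag.tmean(x, axis=(2, 3), keepdims=True)
        xc = x - mu
        var = ag.tmean(xc * xc, axis=(2, 3), keepdims=True)
        xn = ag.div(xc, ag.sqrt(var + self.eps))
        c = self.gamma.data.shape[0]
        return xn * ag.reshape(self.gamma, (1, c, 1, 1)) \
            + ag.reshape(self.beta, (1, c, 1, 1))


class ConvNormRelu(Module):
    """Conv -> instance norm -> ReLU, the package's standard conv block."""

    def __init__(self, cin: int, cout: int, k: int, *, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.conv = Conv2d(cin, cout, k, stride=stride, rng=rng)
        self.norm = InstanceNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.norm(self.conv(x)))


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            if callable(layer) and not isinstance(layer, Module):
                x = layer(x)
            else:
                x = layer(x)
        return x


class Adam:
    """Adam with the standard bias correction; state keyed per parameter."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
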