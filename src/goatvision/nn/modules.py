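"""Neural-network module system: parameter containers, conv/BN layers, Adam."""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Minimal module container with named-parameter traversal."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def count_parameters(self) -> int:
        """Exact count of trainable scalar weights."""
        return int(sum(p.size for p in self.parameters()))

    def initialize(self, seed: int = 0) -> "Module":
        """Deterministically (re)initialize all weights from ``seed``.

        Convolutions get Kaiming-normal weights (fan-in), biases 0; batch
        norms get unit weight / zero bias and reset running statistics.
        Traversal order is insertion order, so the mapping from seed to
        weights is reproducible.
        """
        rng = np.random.default_rng(seed)
        for m in self.modules():
            if isinstance(m, Conv2d):
                fan_in = m.weight.data[0].size
                std = np.sqrt(2.0 / fan_in)
                m.weight.data[...] = rng.normal(0.0, std, m.weight.shape)
                if m.bias is not None:
                    m.bias.data[...] = 0.0
            elif isinstance(m, BatchNorm2d):
                m.weight.data[...] = 1.0
                m.bias.data[...] = 0.0
                m.running_mean[...] = 0.0
                m.running_var[...] = 1.0
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                out[f"__bnstats.{i}.mean"] = m.running_mean.copy()
                out[f"__bnstats.{i}.var"] = m.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean[...] = state[f"__bnstats.{i}.mean"]
                m.running_var[...] = state[f"__bnstats.{i}.var"]


class ModuleList(Module):
    def __init__(self, items=()):
        super().__init__()
        self.items = list(items)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m: Module):
        self.items.append(m)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _param(shape, dtype=np.float32) -> Tensor:
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 padding: Optional[int] = None, groups: int = 1,
                 bias: bool = False):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError("channels must be divisible by groups")
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        self.weight = _param((cout, cin // groups, k, k))
        self.bias = _param((cout,)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = _param((channels,))
        self.bias = _param((channels,))
        self.weight.data[...] = 1.0
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = self.weight.shape[0]
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            # build the normalization with tape ops so gradients flow through
            # the batch statistics
            mu = T.tmean(x, axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            v = T.tmean(xc * xc, axis=(0, 2, 3), keepdims=True)
            xhat = xc / T.sqrt(v + self.eps)
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - Tensor(mu)) / Tensor(sd)
        w = T.reshape(self.weight, (1, c, 1, 1))
        b = T.reshape(self.bias, (1, c, 1, 1))
        return xhat * w + b


class SiLU(Module):
    def forward(self, x):
        return T.silu(x)


class ConvBN(Module):
    """Convolution + batch norm + SiLU — the detector's standard conv unit."""

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 padding: Optional[int] = None, groups: int = 1,
                 act: bool = True):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        return T.silu(x) if self.act else x


class Adam:
    """Adam with decoupled-free L2 weight decay (added to the gradient)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
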