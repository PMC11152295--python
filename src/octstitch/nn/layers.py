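"""Neural-network layers on top of the autograd engine.

Layers follow torch-like semantics (train/eval modes, running batch-norm
statistics, state_dict round-trips) so the backbone code reads the way the
field writes vision models.
"""
from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import DTYPE, Tensor

_global_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the generator used for parameter init and stochastic layers."""
    global _global_rng
    _global_rng = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _global_rng


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- registry ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).items():
            pass
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value

    # -- modes ------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in own:
                if own[name].shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{own[name].shape} vs {arr.shape}")
                own[name].data = np.asarray(arr, dtype=DTYPE).copy()
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unexpected key in state dict: {name}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        if padding is None:
            padding = kernel_size // 2
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        std = math.sqrt(2.0 / fan_in)  # Kaiming for ReLU nets
        self.weight = Parameter(_global_rng.normal(
            0.0, std, (out_channels, in_channels // groups,
                       kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, groups=self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(_global_rng.uniform(
            -bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean += self.momentum * (
                mean.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
            inv = ag.power(var + self.eps, -0.5)
            xhat = centered * inv
        else:
            mean = self.running_mean.reshape(1, -1, 1, 1)
            inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(
                1, -1, 1, 1)
            xhat = (x - Tensor(mean)) * Tensor(inv)
        w = self.weight.reshape(1, self.num_features, 1, 1)
        b = self.bias.reshape(1, self.num_features, 1, 1)
        return xhat * w + b


class LayerNorm(Module):
    """Normalization over the last axis (used on pooled feature vectors)."""

    def __init__(self, num_features: int, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        centered = x - mean
        var = (centered * centered).mean(axis=-1, keepdims=True)
        xhat = centered * ag.power(var + self.eps, -0.5)
        return xhat * self.weight + self.bias


class AvgPool2d(Module):
    def __init__(self, stride: int):
        super().__init__()
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return ag.avg_pool2d(x, self.stride)


class DropPath(Module):
    """Stochastic depth: drop the whole residual branch per sample."""

    def __init__(self, drop_prob: float = 0.0):
        super().__init__()
        self.drop_prob = float(drop_prob)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.drop_prob == 0.0:
            return x
        keep = 1.0 - self.drop_prob
        shape = (x.shape[0],) + (1,) * (x.ndim - 1)
        mask = (_global_rng.random(shape) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)
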