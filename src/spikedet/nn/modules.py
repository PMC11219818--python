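"""Layer abstractions over the autodiff engine.

Follows the familiar Module/Parameter idiom: a :class:`Module` owns named
parameters and submodules, exposes ``state_dict``/``load_state_dict`` for
checkpointing, and toggles train/eval behaviour (batch-norm statistics).
Convolutions use He-uniform initialisation; batch norm starts at the
identity transform.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "BatchNorm2d", "GroupNorm",
    "ReLU", "Identity",
]


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        seen = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    # -- serialization ----------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m._named_buffers(prefix + name + ".")

    def state_dict(self) -> dict:
        sd = {k: v.data.copy() for k, v in self.named_parameters()}
        sd.update({k: np.array(v, dtype=np.float32, copy=True)
                   for k, v in self._named_buffers()})
        return sd

    def load_state_dict(self, sd: dict):
        own = dict(self.named_parameters())
        bufs = dict(self._named_buffers())
        missing = (set(own) | set(bufs)) - set(sd)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)[:5]}")
        for k, p in own.items():
            arr = np.asarray(sd[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr
        for k in bufs:
            target = self
            *path, leaf = k.split(".")
            for part in path:
                target = target._modules[part]
            setattr(target, leaf, np.asarray(sd[k], dtype=np.float32).copy())

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)

    def forward(self, *args, **kw):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride=1, padding=0, dilation=1, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else tuple(kernel_size)
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = (kh, kw)
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        rng = rng or np.random.default_rng()
        fan_in = (in_channels // groups) * kh * kw
        bound = math.sqrt(6.0 / fan_in)  # He-uniform
        self.weight = Tensor(
            rng.uniform(-bound, bound,
                        (out_channels, in_channels // groups, kh, kw)
                        ).astype(np.float32),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding,
                        self.dilation, self.groups)


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features, self.eps, self.momentum = num_features, eps, momentum
        self.gamma = Tensor(np.ones(num_features, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = self.num_features
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
            self.running_mean += self.momentum * (mu.data.reshape(c) - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class GroupNorm(Module):
    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError("channels must be divisible by groups")
        self.num_groups, self.num_channels, self.eps = num_groups, num_channels, eps
        self.gamma = Tensor(np.ones(num_channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.num_groups
        xg = x.reshape(n, g, c // g, h, w)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=(2, 3, 4), keepdims=True)
        xhat = ((xg - mu) / (var + self.eps).sqrt()).reshape(n, c, h, w)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
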