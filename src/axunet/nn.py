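"""Neural-network building blocks over :mod:`axunet.autodiff`.

Provides the module/parameter system, the layers the segmentation network is
assembled from (convolution, batch/layer normalization, linear maps, pooling,
bilinear upsampling), SGD with momentum, and the cosine-annealing
warm-restart learning-rate schedule.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "Identity",
    "ReLU",
    "GELU",
    "avg_pool2x",
    "global_avg_pool",
    "seed_all",
    "default_rng",
    "SGD",
    "CosineAnnealingWarmRestarts",
]

_rng = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Seed the generator used for parameter initialization."""
    global _rng
    _rng = np.random.default_rng(seed)


def default_rng() -> np.random.Generator:
    return _rng


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: attribute registration, traversal, state dicts, modes."""

    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{key}.")
            elif name in getattr(self, "_buffers", ()):
                yield key, value

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)[:5]}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                )
            p.data = state[name].astype(np.float32).copy()
        # buffers (running stats) are restored by attribute walk
        self._load_buffers(state, "")

    def _load_buffers(self, state, prefix):
        for name, value in list(vars(self).items()):
            key = f"{prefix}{name}"
            if isinstance(value, Module):
                value._load_buffers(state, f"{key}.")
            elif name in getattr(self, "_buffers", ()) and key in state:
                setattr(self, name, state[key].astype(np.float32).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._n = len(list(mods))

    def __iter__(self):
        return (getattr(self, str(i)) for i in range(self._n))

    def __len__(self):
        return self._n

    def __getitem__(self, i):
        return getattr(self, str(i % self._n if self._n else 0))

    def append(self, m: Module) -> None:
        setattr(self, str(self._n), m)
        self._n += 1


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.layers = ModuleList(mods)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class GELU(Module):
    def forward(self, x):
        return ad.gelu(x)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        bound = math.sqrt(6.0 / (in_features + out_features))
        self.weight = Parameter(_rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        y = ad.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        std = math.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.weight = Parameter(_rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel, with running stats."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")
        self.eps = eps
        self.momentum = momentum

    def forward(self, x):
        C = x.shape[1]
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            m, v = mean.data.reshape(-1), var.data.reshape(-1)
            n = x.data.size / C
            self.running_mean += self.momentum * (m - self.running_mean)
            self.running_var += self.momentum * (v * n / max(n - 1, 1) - self.running_var)
            xhat = centered * (var + self.eps) ** -0.5
        else:
            mean = self.running_mean.reshape(1, C, 1, 1)
            var = self.running_var.reshape(1, C, 1, 1)
            xhat = (x - Tensor(mean)) * Tensor(1.0 / np.sqrt(var + self.eps))
        w = self.weight.reshape((1, C, 1, 1))
        b = self.bias.reshape((1, C, 1, 1))
        return xhat * w + b


class LayerNorm(Module):
    """Layer normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x):
        mean = x.mean(axis=-1, keepdims=True)
        centered = x - mean
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.weight + self.bias


def avg_pool2x(x) -> Tensor:
    """2x2 average pooling with stride 2 (extents must be even)."""
    B, C, H, W = x.shape
    return x.reshape((B, C, H // 2, 2, W // 2, 2)).mean(axis=(3, 5))


def global_avg_pool(x) -> Tensor:
    """Spatial global average pooling: [B,C,H,W] -> [B,C]."""
    return x.mean(axis=(2, 3))


# ----------------------------------------------------------------------
# optimization
class SGD:
    """SGD with momentum and decoupled-from-nothing classic weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class CosineAnnealingWarmRestarts:
    """Cosine-annealed learning rate with warm restarts.

    Within a cycle of length T_i the rate follows
    ``eta_min + (eta_max - eta_min) * (1 + cos(pi * t / T_i)) / 2``;
    each restart multiplies the cycle length by ``t_mult``.
    """

    def __init__(self, optimizer: SGD, t0: float, t_mult: float = 1.0,
                 eta_min: float = 0.0):
        if t0 <= 0:
            raise ValueError("t0 must be positive")
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.t0 = float(t0)
        self.t_mult = float(t_mult)
        self.eta_min = eta_min
        self.step(0.0)

    def lr_at(self, epoch: float) -> float:
        t, ti = float(epoch), self.t0
        while t >= ti:
            t -= ti
            ti *= self.t_mult
        return self.eta_min + (self.base_lr - self.eta_min) * (
            1.0 + math.cos(math.pi * t / ti)
        ) / 2.0

    def step(self, epoch: float) -> float:
        lr = self.lr_at(epoch)
        self.optimizer.lr = lr
        return lr
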