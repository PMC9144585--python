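"""Minimal neural-network layer containers on top of the autodiff engine.

Initialisation is He-normal (gain for LeakyReLU nets) from a NumPy
``Generator`` passed at construction, so whole networks are reproducible
from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: tracks parameters and sub-modules by attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + n: p for n, p in self._params.items()}
        for mn, m in self._modules.items():
            out.update(m.named_parameters(prefix + mn + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)[:5]}")
        for n, p in params.items():
            arr = np.asarray(state[n], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {n}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.standard_normal(shape).astype(np.float32) * std, requires_grad=True)


class Conv2d(Module):
    """Stride-1 convolution with symmetric zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = kernel_size // 2
        self.padding = padding
        self.kernel_size = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = _he_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.padding = kernel_size // 2
        self.channels = channels
        self.weight = _he_normal(rng, (channels, kernel_size, kernel_size),
                                 kernel_size * kernel_size)
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv2d(x, self.weight, self.bias, self.padding)


class SeparableConv2d(Module):
    """Depthwise 3x3 followed by pointwise 1x1 — the RDB's convolution type."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.depthwise = DepthwiseConv2d(in_channels, kernel_size, rng)
        self.pointwise = Conv2d(in_channels, out_channels, 1, padding=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = _he_normal(rng, (in_features, out_features), in_features)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.weight), self.bias)
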