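"""Layer objects over :mod:`imau_seg.nn.ops` with seeded initialization."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import ops
from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm",
    "MaxPool2D",
    "AvgPool2D",
    "ConvBNReLU",
    "Sequential",
]


class Module:
    """Base class: parameter discovery and train/eval mode cascade."""

    training: bool = True

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for value in vars(self).values():
            yield from _params_of(value, seen)

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            yield from _modules_of(value)

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    # -- flat state-dict (used for .npz checkpoints) -------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i:05d}"] = p.data
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                out[f"bnmean_{i:05d}"] = m.running_mean
                out[f"bnvar_{i:05d}"] = m.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.ascontiguousarray(state[f"param_{i:05d}"])
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                m.running_mean = np.ascontiguousarray(state[f"bnmean_{i:05d}"])
                m.running_var = np.ascontiguousarray(state[f"bnvar_{i:05d}"])


def _params_of(value, seen: set[int]) -> Iterator[Parameter]:
    if isinstance(value, Parameter):
        if id(value) not in seen:
            seen.add(id(value))
            yield value
    elif isinstance(value, Module):
        for v in vars(value).values():
            yield from _params_of(v, seen)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _params_of(v, seen)


def _modules_of(value) -> Iterator[Module]:
    if isinstance(value, Module):
        yield from value.modules()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _modules_of(v)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2D(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel=3,
        stride=1,
        dilation=1,
        padding: str = "same",
        use_bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        kh, kw = ops._pair(kernel)
        fan_in = kh * kw * in_channels
        self.weight = Parameter(_he_init(rng, (kh, kw, in_channels, out_channels), fan_in))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if use_bias else None
        self.stride, self.dilation, self.padding = stride, dilation, padding

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv2d(
            x, self.weight, self.bias, self.stride, self.dilation, self.padding
        )


class ConvTranspose2D(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel=3,
        stride=2,
        use_bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        kh, kw = ops._pair(kernel)
        fan_in = kh * kw * in_channels
        self.weight = Parameter(_he_init(rng, (kh, kw, in_channels, out_channels), fan_in))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if use_bias else None
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv2d_transpose(x, self.weight, self.bias, self.stride)


class BatchNorm(Module):
    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3) -> None:
        self.gamma = Parameter(np.ones(channels, np.float32))
        self.beta = Parameter(np.zeros(channels, np.float32))
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return ops.batchnorm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class MaxPool2D(Module):
    def __init__(self, kernel=2, stride=1, padding: str = "same") -> None:
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return ops.maxpool2d(x, self.kernel, self.stride, self.padding)


class AvgPool2D(Module):
    def __init__(self, kernel=3, stride=1, padding: str = "same") -> None:
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return ops.avgpool2d(x, self.kernel, self.stride, self.padding)


class ConvBNReLU(Module):
    """conv (no bias) -> batch norm -> ReLU, the backbone's basic unit."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel=3,
        stride=1,
        dilation=1,
        padding: str = "same",
        rng: np.random.Generator | None = None,
    ) -> None:
        self.conv = Conv2D(
            in_channels, out_channels, kernel, stride, dilation, padding,
            use_bias=False, rng=rng,
        )
        self.bn = BatchNorm(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return ops.relu(self.bn(self.conv(x)))


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
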