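"""Layer primitives for the restoration networks.

A deliberately small module system: parameters are Tensors with
``requires_grad=True``; ``Module.parameters()`` walks attributes
recursively.  Initialization draws from an explicit
``numpy.random.Generator`` so two builds from the same seed produce
identical parameter tensors.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ReLU", "Sequential"]


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            for m in _collect_modules(value):
                mods.append(m)
        return mods

    def train_mode(self, flag: bool = True) -> None:
        for m in self.modules():
            if hasattr(m, "training"):
                m.training = flag

    def eval_mode(self) -> None:
        self.train_mode(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.data.copy()
        for j, (m, name, buf) in enumerate(self._buffers()):
            state[f"buffer_{j}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"param_{i}"], dtype=np.float64).copy()
        for j, (m, name, _) in enumerate(self._buffers()):
            setattr(m, name, np.asarray(state[f"buffer_{j}"], dtype=np.float64).copy())

    def _buffers(self) -> list[tuple["Module", str, np.ndarray]]:
        bufs = []
        for m in self.modules():
            for name in getattr(m, "_buffer_names", ()):
                bufs.append((m, name, getattr(m, name)))
        return bufs

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _collect_modules(value):
    if isinstance(value, Module):
        yield value
        for v in vars(value).values():
            yield from _collect_modules(v)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect_modules(v)


class Conv2d(Module):
    """3x3 (or kxk) convolution with He-normal initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None,
                 weight_scale: float = 1.0, bias: bool = True):
        if padding is None:
            padding = kernel_size // 2
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = weight_scale * np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(out_channels, in_channels,
                                       kernel_size, kernel_size))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    Composed from autograd primitives, so the backward pass needs no
    bespoke derivation.  Running statistics are plain numpy buffers used
    in evaluation mode.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            inv = (var + self.eps) ** -0.5
            return centered * inv * self.gamma + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - Tensor(self.running_mean)) * Tensor(inv) * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
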