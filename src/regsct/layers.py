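"""Trainable layers built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .errors import ShapeError


class Module:
    """Base class: recursive parameter collection and gradient reset."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ShapeError(f"checkpoint holds {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ShapeError(f"parameter shape {p.data.shape} != stored {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 init_std: float = 0.02, zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((out_ch, in_ch, kernel, kernel), dtype=np.float32)
        else:
            w = rng.normal(0.0, init_std, (out_ch, in_ch, kernel, kernel)).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 2,
                 padding: int = 1, output_padding: int = 1,
                 rng: np.random.Generator | None = None, init_std: float = 0.02):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, init_std, (in_ch, out_ch, kernel, kernel)).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))
        self.stride = stride
        self.padding = padding
        self.output_padding = output_padding

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                   self.padding, self.output_padding)


class InstanceNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ad.instance_norm2d(x, self.gamma, self.beta, self.eps)
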