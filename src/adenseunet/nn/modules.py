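"""Layer modules (parameter containers) for the NumPy autodiff engine."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v
            elif isinstance(value, dict):
                for v in value.values():
                    if isinstance(v, Module):
                        yield v

    def parameters(self):
        seen = set()
        for value in self.__dict__.values():
            if isinstance(value, Parameter) and id(value) not in seen:
                seen.add(id(value))
                yield value
        for child in self._children():
            for p in child.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    yield p

    def train(self):
        self.training = True
        for child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for child in self._children():
            child.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        """All parameter arrays plus batch-norm running statistics, in a
        stable discovery order (used for checkpointing)."""
        arrays = [p.data for p in self.parameters()]
        stack = [self]
        while stack:
            m = stack.pop()
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
            stack.extend(m._children())
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(arrays, state):
            if dst.shape != src.shape:
                raise ValueError("state shape mismatch")
            dst[...] = src


class Conv2d(Module):
    """Convolution with SAME zero-padding by default (He-normal init)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        dilation: int = 1,
        bias: bool = True,
        zero_init: bool = False,
    ):
        super().__init__()
        self.stride = stride
        self.dilation = dilation
        self.kernel = kernel
        fan_in = in_channels * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        w = np.zeros((out_channels, in_channels, kernel, kernel)) if zero_init else (
            rng.normal(0.0, std, (out_channels, in_channels, kernel, kernel))
        )
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        _, _, H, W = x.shape
        pt, pb = F.same_padding(H, self.kernel, self.stride, self.dilation)
        pl, pr = F.same_padding(W, self.kernel, self.stride, self.dilation)
        return F.conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            dilation=self.dilation,
            padding=(pt, pb, pl, pr),
        )


class ConvTranspose2d(Module):
    """Transposed convolution, kernel = stride = 2 (exact x2 upsampling)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        factor: int = 2,
        bias: bool = True,
    ):
        super().__init__()
        self.factor = factor
        std = np.sqrt(2.0 / in_channels)
        self.weight = Parameter(
            rng.normal(0.0, std, (in_channels, out_channels, factor, factor))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, factor=self.factor)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.sigmoid(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
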