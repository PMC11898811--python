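"""Neural-network building blocks on top of the autograd engine.

Initialization follows He fan-in scaling for convolutions and Glorot for
linear projections, drawn from an explicit numpy Generator so model
construction is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "Dropout",
    "Linear",
]


class Module:
    """Base class with parameter discovery and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- (de)serialization -------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        """All parameter and buffer arrays in discovery order."""
        out = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                out.extend([m.running_mean, m.running_var])
        return out

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for p in self.parameters():
            a = next(it)
            if a.shape != p.data.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = a.astype(np.float64)
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = next(it).astype(np.float64)
                m.running_var = next(it).astype(np.float64)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0, scale, (out_ch, in_ch, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (kernel * kernel))
        self.weight = Tensor(
            rng.normal(0, scale, (channels, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(channels), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.depthwise_conv2d(self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = x.batch_norm(self.gamma, self.beta, self.eps)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            return out
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        shift = self.beta.data - self.running_mean * scale
        return x * Tensor(scale[None, :, None, None]) + Tensor(shift[None, :, None, None])


class Dropout(Module):
    def __init__(self, p: float, *, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (in_f + out_f))
        self.weight = Tensor(rng.normal(0, scale, (in_f, out_f)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x.matmul(self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y
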