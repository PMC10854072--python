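"""Trainable layers composed from the autodiff ops.

A :class:`Module` owns named parameters and named sub-modules; iteration
order is insertion order, which makes parameter registries, summaries and
weight archives deterministic.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    # -- registration -------------------------------------------------
    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield (prefix + name, b)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def named_modules(self, prefix: str = ""):
        yield (prefix.rstrip("."), self)
        for name, m in self._modules.items():
            yield from m.named_modules(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own_p = dict(self.named_parameters())
        own_b = dict(self.named_buffers())
        missing = (set(own_p) | set(own_b)) - set(state)
        extra = set(state) - (set(own_p) | set(own_b))
        if missing or extra:
            raise ValueError(
                f"state mismatch: missing {sorted(missing)[:5]}, unexpected {sorted(extra)[:5]}")
        for name, p in own_p.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{p.data.shape} vs {state[name].shape}")
            p.data = state[name].astype(p.data.dtype, copy=True)
        for name, b in own_b.items():
            b[...] = state[name]

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def _uniform_fan_init(rng: np.random.Generator, shape, fan_in: int,
                      dtype=np.float32) -> np.ndarray:
    # He-style uniform: U(-sqrt(6/fan_in), +sqrt(6/fan_in))
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv(Module):
    """Size-preserving convolution; kernel extent 1 or 3 per axis."""

    def __init__(self, rank: int, in_channels: int, out_channels: int,
                 kernel: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.rank, self.in_channels, self.out_channels = rank, in_channels, out_channels
        self.kernel = kernel
        fan_in = (kernel ** rank) * in_channels
        self.weight = Parameter(_uniform_fan_init(
            rng, (kernel,) * rank + (in_channels, out_channels), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv(x, self.weight, self.bias)


class ConvTranspose2x(Module):
    """Learnable 2x upsampling: transposed conv, kernel 2 per axis, stride 2."""

    def __init__(self, rank: int, in_channels: int, out_channels: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.rank, self.in_channels, self.out_channels = rank, in_channels, out_channels
        self.kernel = 2
        self.weight = Parameter(_uniform_fan_init(
            rng, (in_channels, (2 ** rank) * out_channels), in_channels))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv_transpose2x(x, self.weight, self.bias)


class BatchNorm(Module):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)
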