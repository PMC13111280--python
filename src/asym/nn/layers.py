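"""Module system and standard layers (torch-like, numpy-backed).

Every layer takes an explicit ``numpy.random.Generator`` for parameter
initialisation so whole models are reproducible from a single seed.
Sequence tensors are (B, T, C).
"""

from __future__ import annotations

import math

import numpy as np

from . import ops
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class; children and parameters are discovered via attributes."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal ------------------------------------------------------
    def named_children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        """Yield (name, parameter); shared parameters appear once per owner."""
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield (f"{prefix}{name}", val)
        for name, child in self.named_children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        """Unique trainable parameters (shared ones deduplicated)."""
        out, seen = [], set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self):
        self.training = True
        for _, c in self.named_children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self.named_children():
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state ----------------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for name, p in self.named_parameters():
            state.setdefault(name, p.data)
        self._collect_buffers(state, prefix="")
        return state

    def _collect_buffers(self, state: dict, prefix: str):
        for k, v in self.buffers().items():
            state[f"{prefix}{k}"] = v
        for name, child in self.named_children():
            child._collect_buffers(state, prefix=f"{prefix}{name}.")

    def buffers(self) -> dict:
        return {}

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.data.shape)
        self._load_buffers(state, prefix="")

    def _load_buffers(self, state: dict, prefix: str):
        for k in self.buffers():
            key = f"{prefix}{k}"
            if key in state:
                getattr(self, k)[...] = state[key]
        for name, child in self.named_children():
            child._load_buffers(state, prefix=f"{prefix}{name}.")

    # -- profiling -------------------------------------------------------
    def flops(self, T: int) -> float:
        """Analytic forward FLOPs at sequence length T (2 x MAC convention)."""
        return float(sum(c.flops(T) for _, c in self.named_children()))


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int):
    bound = math.sqrt(1.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Linear(Module):
    """Per-step affine map; equivalently a 1x1 convolution over time."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming_uniform(rng, (in_features, out_features),
                                                 in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y

    def flops(self, T: int) -> float:
        return 2.0 * T * self.in_features * self.out_features


class Conv1d(Module):
    """Dense temporal convolution, stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, padding: str = "same",
                 bias: bool = True, dilation: int = 1):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.padding = padding
        self.dilation = dilation
        self.weight = Parameter(_kaiming_uniform(
            rng, (out_channels, in_channels, kernel), in_channels * kernel))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv1d(x, self.weight, self.bias, padding=self.padding,
                          dilation=self.dilation)

    def flops(self, T: int) -> float:
        return 2.0 * T * self.in_channels * self.out_channels * self.kernel


class DepthwiseConv1d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 padding: str = "causal", bias: bool = True, dilation: int = 1):
        super().__init__()
        self.channels = channels
        self.kernel = kernel
        self.padding = padding
        self.dilation = dilation
        self.weight = Parameter(_kaiming_uniform(rng, (channels, kernel), kernel))
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv1d_depthwise(x, self.weight, self.bias,
                                    padding=self.padding,
                                    dilation=self.dilation)

    def flops(self, T: int) -> float:
        return 2.0 * T * self.channels * self.kernel


class LayerNorm(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        return ops.layer_norm(x, self.gamma, self.beta, eps=self.eps)

    def flops(self, T: int) -> float:
        return 8.0 * T * self.channels


class BatchNorm1d(Module):
    """Normalises per channel over (batch, time); tracks running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.channels = channels

    def buffers(self) -> dict:
        return {"running_mean": self.running_mean,
                "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        return ops.batch_norm(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, training=self.training,
                              momentum=self.momentum, eps=self.eps)

    def flops(self, T: int) -> float:
        return 4.0 * T * self.channels


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return ops.dropout(x, self.rate, self.rng, training=self.training)

    def flops(self, T: int) -> float:
        return 0.0


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
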