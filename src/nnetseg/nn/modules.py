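"""Layer modules: parameter containers with a ``__call__`` forward.

Modules own their parameters as :class:`Tensor` objects and register
sub-modules by attribute assignment, so ``parameters()`` and
``state_dict()`` walk the whole tree.  Weight initialisation is
He-uniform for convolution kernels and zeros for biases, drawn from the
``rng`` handed to each layer so a model build is reproducible from a
single seed.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import functional as F
from .tensor import Tensor

DTYPE = np.float32


class Module:
    def __init__(self):
        self._params: "OrderedDict[str, Tensor]" = OrderedDict()
        self._buffers: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self._modules: "OrderedDict[str, Module]" = OrderedDict()
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=DTYPE), requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=DTYPE)
        self._buffers[name] = arr
        return arr

    # -- tree walking ----------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialisation -----------------------------------------------------

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        state = OrderedDict()
        for name, p in self.named_parameters():
            state[name] = p.data.copy()
        for name, b in self.named_buffers():
            state["buffer:" + name] = b.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{p.data.shape} vs {value.shape}")
                p.data = np.asarray(value, dtype=DTYPE).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    """Stride-1 square convolution; padding defaults to the 'same' value
    ``dilation * (k - 1) // 2`` so spatial size is preserved for odd k."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ValueError("kernel_size must be odd and >= 1")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.padding = dilation * (kernel_size - 1) // 2 if padding is None else padding
        fan_in = in_channels * kernel_size ** 2
        bound = np.sqrt(6.0 / fan_in)  # He-uniform
        self.weight = self.register_parameter(
            "weight", rng.uniform(-bound, bound,
                                  (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = self.register_parameter("bias", np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias,
                        dilation=self.dilation, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = self.register_parameter("gamma", np.ones(num_features))
        self.beta = self.register_parameter("beta", np.zeros(num_features))
        self.running_mean = self.register_buffer("running_mean", np.zeros(num_features))
        self.running_var = self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(x, self.gamma, self.beta,
                              self.running_mean, self.running_var,
                              training=self.training, momentum=self.momentum,
                              eps=self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.sigmoid(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def count_parameters(module: Module) -> int:
    """Total number of learnable scalars in a module tree."""
    return int(sum(p.data.size for p in module.parameters()))
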