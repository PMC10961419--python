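"""Neural-network building blocks over the autodiff core.

Conventions follow common CNN practice: He-normal initialization for
convolutions and linear layers, batch norm with running statistics
(momentum 0.1, eps 1e-5), and a ``decay`` flag on parameters so the optimizer
can restrict weight decay to conv/linear weights.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True):
        super().__init__(data, requires_grad=True)
        self.decay = decay


class Module:
    def __init__(self):
        self._params: OrderedDict[str, Parameter] = OrderedDict()
        self._modules: OrderedDict[str, Module] = OrderedDict()
        self._buffers: OrderedDict[str, np.ndarray] = OrderedDict()
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- state ------------------------------------------------------------
    def state_dict(self, prefix: str = "", out: dict | None = None) -> dict:
        out = {} if out is None else out
        for name, p in self._params.items():
            out[prefix + name] = p.data.copy()
        for name, b in self._buffers.items():
            out[prefix + name] = np.asarray(getattr(self, name)).copy()
        for name, m in self._modules.items():
            m.state_dict(prefix + name + ".", out)
        return out

    def load_state_dict(self, state: dict, prefix: str = "") -> None:
        for name, p in self._params.items():
            p.data = state[prefix + name].copy()
        for name in self._buffers:
            val = state[prefix + name].copy()
            self._buffers[name] = val
            object.__setattr__(self, name, val)
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)

    def forward(self, x):
        for m in self._modules.values():
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Conv2d(Module):
    def __init__(self, in_c: int, out_c: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = (in_c // groups) * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.standard_normal((out_c, in_c // groups, kernel, kernel)) * scale
        )
        self.bias = Parameter(np.zeros(out_c), decay=False) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels), decay=False)
        self.beta = Parameter(np.zeros(channels), decay=False)
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        c = x.data.shape[1]
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - m
            v = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            rm = self._buffers["running_mean"]
            rv = self._buffers["running_var"]
            rm += self.momentum * (m.data.reshape(c) - rm)
            rv += self.momentum * (v.data.reshape(c) - rv)
            xhat = xc / (v + self.eps).sqrt()
        else:
            m = self._buffers["running_mean"].reshape(1, c, 1, 1)
            v = self._buffers["running_var"].reshape(1, c, 1, 1)
            xhat = (x - Tensor(m)) / Tensor(np.sqrt(v + self.eps))
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.standard_normal((in_f, out_f)) * np.sqrt(2.0 / in_f))
        self.bias = Parameter(np.zeros(out_f), decay=False) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1)
        return out


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return F.avg_pool2d(x, self.kernel, self.stride, self.padding)


class GlobalAvgPool(Module):
    def forward(self, x):
        return x.mean(axis=(2, 3))


def conv_bn_relu(in_c, out_c, kernel, *, stride=1, padding=0, groups=1,
                 relu=True, rng=None) -> Sequential:
    mods = [
        Conv2d(in_c, out_c, kernel, stride=stride, padding=padding,
               groups=groups, rng=rng),
        BatchNorm2d(out_c),
    ]
    if relu:
        mods.append(ReLU())
    return Sequential(*mods)
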