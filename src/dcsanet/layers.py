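"""Layer abstractions over the autograd core.

Every layer knows three things: how to run forward on a ``Var``, how many
multiply-accumulates it spends on a given input shape (``macs``), and the
shape it produces (``out_shape``).  The cost accounting convention is the one
used throughout the package: one FLOP per multiply-accumulate, convolution
and linear layers only (normalisation, activations, pooling and resampling
are free).
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Var

__all__ = [
    "Module",
    "Parameter",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "BilinearUpsample",
    "Sequential",
]


class Parameter(Var):
    """A trainable leaf variable."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _kaiming(rng, shape, fan_in):
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Module:
    """Base class; subclasses register parameters/buffers/children as attributes."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._children: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix=f"{prefix}{cname}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_params(self):
        return sum(p.data.size for p in self.parameters())

    # -- state io ----------------------------------------------------------
    def state_dict(self):
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        for name, mod in self._named_modules():
            for bname in getattr(mod, "_buffers", ()):
                key = f"buffer:{name}{bname}" if name else f"buffer:{bname}"
                state[key] = getattr(mod, bname)
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unexpected parameter {name!r}")
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = np.array(value)
            elif kind == "buffer":
                *mod_path, bname = name.split(".")
                mod = self
                for part in mod_path:
                    mod = mod._children[part]
                getattr(mod, bname)[...] = value

    def _named_modules(self, prefix=""):
        yield prefix, self
        for cname, child in self._children.items():
            yield from child._named_modules(prefix=f"{prefix}{cname}.")

    # -- contracts subclasses fill in --------------------------------------
    def forward(self, x: Var) -> Var:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def out_shape(self, shape):
        """(C, H, W) -> (C, H, W) after this layer."""
        return shape

    def macs(self, shape):
        """Multiply-accumulates spent on one sample of input ``shape``."""
        return 0


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, bias=False, rng=None):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel = (kh, kw)
        self.stride = stride
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels, kh, kw), in_channels * kh * kw))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, bias=self.bias, stride=self.stride)

    def out_shape(self, shape):
        c, h, w = shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        s = self.stride
        return (self.out_channels, -(-h // s), -(-w // s))

    def macs(self, shape):
        _, ho, wo = self.out_shape(shape)
        kh, kw = self.kernel
        return ho * wo * kh * kw * self.in_channels * self.out_channels


class DepthwiseConv2d(Module):
    """One spatial filter per channel; kernel may be asymmetric (N,1)/(1,N)."""

    def __init__(self, channels, kernel_size, stride=1, rng=None):
        super().__init__()
        kh, kw = kernel_size
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.kernel = (kh, kw)
        self.stride = stride
        self.weight = Parameter(_kaiming(rng, (channels, kh, kw), kh * kw))

    def forward(self, x):
        return ag.depthwise_conv2d(x, self.weight, stride=self.stride)

    def out_shape(self, shape):
        c, h, w = shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        s = self.stride
        return (c, -(-h // s), -(-w // s))

    def macs(self, shape):
        _, ho, wo = self.out_shape(shape)
        kh, kw = self.kernel
        return ho * wo * kh * kw * self.channels


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x):
        return ag.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class MaxPool2d(Module):
    """2x2 max pooling with stride 2."""

    def forward(self, x):
        return ag.max_pool2x2(x)

    def out_shape(self, shape):
        c, h, w = shape
        return (c, h // 2, w // 2)


class BilinearUpsample(Module):
    def __init__(self, scale):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        _, _, h, w = x.data.shape
        return ag.bilinear_resize(x, (h * self.scale, w * self.scale))

    def out_shape(self, shape):
        c, h, w = shape
        return (c, h * self.scale, w * self.scale)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def out_shape(self, shape):
        for layer in self.layers:
            shape = layer.out_shape(shape)
        return shape

    def macs(self, shape):
        total = 0
        for layer in self.layers:
            total += layer.macs(shape)
            shape = layer.out_shape(shape)
        return total
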