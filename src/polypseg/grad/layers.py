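"""Minimal layer/module system on top of the autodiff engine."""

from __future__ import annotations

import math

import numpy as np

from . import engine
from .engine import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter/submodule discovery.

    Children are found by scanning ``__dict__`` in insertion order, so
    parameter ordering (and therefore optimizer state and checkpoints) is
    deterministic.
    """

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def children(self):
        for name, value in self.__dict__.items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, value in self.__dict__.items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_modules(self, prefix=""):
        yield prefix.rstrip("."), self
        for name, child in self.children():
            yield from child.named_modules(prefix + name + ".")

    def train(self, mode=True):
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self):
        return sum(p.data.size for p in self.parameters())

    def state_dict(self, prefix=""):
        state = {prefix + n: p.data.copy() for n, p in self.named_parameters()}
        for name, mod in self.named_modules():
            if isinstance(mod, BatchNorm2d):
                key = (prefix + name + ".") if name else prefix
                state[key + "running_mean"] = mod.running_mean.copy()
                state[key + "running_var"] = mod.running_var.copy()
        return state

    def load_state_dict(self, state, strict=True):
        own = dict(self.named_parameters())
        for name, mod in self.named_modules():
            if isinstance(mod, BatchNorm2d):
                key = (name + ".") if name else ""
                own[key + "running_mean"] = mod.running_mean
                own[key + "running_var"] = mod.running_var
        missing = [k for k in own if k not in state]
        unexpected = [k for k in state if k not in own]
        if strict and (missing or unexpected):
            raise KeyError(f"state mismatch: missing={missing}, unexpected={unexpected}")
        for k, target in own.items():
            if k not in state:
                continue
            src = np.asarray(state[k])
            if isinstance(target, Parameter):
                if target.data.shape != src.shape:
                    raise ValueError(f"shape mismatch for {k}: "
                                     f"{target.data.shape} vs {src.shape}")
                target.data = src.astype(target.data.dtype)
            else:  # running statistic buffer: update in place
                target[...] = src
        return missing, unexpected


class Conv2d(Module):
    """2-D convolution; He-normal weight init, optional bias."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k * k
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return engine.conv2d(x, self.weight, self.bias,
                             stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return engine.batchnorm2d(x, self.weight, self.bias,
                                  self.running_mean, self.running_var,
                                  momentum=self.momentum, eps=self.eps,
                                  training=self.training)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return engine.relu(x)


def conv_bn_relu(in_ch, out_ch, kernel, stride=1, padding=0, rng=None):
    """The ubiquitous conv → batchnorm → ReLU stack (conv without bias)."""
    return Sequential(
        Conv2d(in_ch, out_ch, kernel, stride=stride, padding=padding,
               bias=False, rng=rng),
        BatchNorm2d(out_ch),
        ReLU(),
    )
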