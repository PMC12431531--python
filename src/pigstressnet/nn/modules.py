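"""Layer/module abstractions over the autograd engine.

The conventions mirror the YOLO family's building blocks: ``Conv`` is a
convolution + batch norm + activation triple whose batch norm is folded
into the convolution at deployment (the fused parameter count is what
model summaries print), while ``PlainConv2d`` and ``BatchNorm2d`` are the
bare layers used inside third-party-style blocks that a fuse pass leaves
untouched.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter / submodule discovery."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- deployed (inference-time) parameter accounting -------------------
    def deployed_param_count(self) -> int:
        """Number of scalars the deployed module carries.

        Default: raw trainable parameters of this module's direct
        attributes plus recursive children.  Layers that fold at
        deployment (``Conv``) override this.
        """
        total = 0
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                total += val.data.size
            elif isinstance(val, Module):
                total += val.deployed_param_count()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        total += item.deployed_param_count()
        return total

    def state_arrays(self, prefix=""):
        """All persistent arrays (parameters and buffers) for checkpointing."""
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val.data
            elif isinstance(val, np.ndarray):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.state_arrays(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.state_arrays(f"{prefix}{name}.{i}.")

    def load_state(self, arrays: dict, prefix=""):
        for name, val in list(vars(self).items()):
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                val.data = arrays[key].astype(np.float32)
            elif isinstance(val, np.ndarray):
                setattr(self, name, arrays[key].astype(np.float32))
            elif isinstance(val, Module):
                val.load_state(arrays, key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        item.load_state(arrays, f"{key}.{i}.")


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.items = list(mods)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m):
        self.items.append(m)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.items = list(mods)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Identity(Module):
    def forward(self, x):
        return x


def autopad(k, p=None):
    if p is not None:
        return p
    if isinstance(k, int):
        return k // 2
    return (k[0] // 2, k[1] // 2)


def _khkw(k):
    return (k, k) if isinstance(k, int) else tuple(k)


def _kaiming(shape, fan_in, rng):
    bound = np.sqrt(2.0 / fan_in)
    return rng.standard_normal(shape).astype(np.float32) * bound


_INIT_RNG = np.random.default_rng(0)


def set_init_seed(seed: int) -> None:
    """Reseed the weight-initialisation stream (call before building a model)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


ACTS = {
    "silu": T.silu,
    "relu": T.relu,
    "relu6": T.relu6,
    "gelu": T.gelu,
    "sigmoid": T.sigmoid,
    None: lambda x: x,
}


class PlainConv2d(Module):
    """Bare convolution (optionally biased), no norm, no activation."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, bias=True):
        super().__init__()
        self.c1, self.c2, self.k, self.s, self.g = c1, c2, k, s, g
        self.p = autopad(k, p)
        kh, kw = _khkw(k)
        self.weight = Parameter(_kaiming((c2, c1 // g, kh, kw), c1 // g * kh * kw, _INIT_RNG))
        self.bias = Parameter(np.zeros(c2)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.s, self.p, self.g)

    def macs(self, ho, wo):
        kh, kw = _khkw(self.k)
        return kh * kw * self.c1 * self.c2 // self.g * ho * wo


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        return T.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class Conv(Module):
    """Framework-style Conv block: conv(bias-free) + BN + activation.

    At deployment the BN folds into the convolution, so the deployed
    parameter count is ``weights + c2`` (one bias per output channel)
    rather than ``weights + 2*c2``.
    """

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act="silu"):
        super().__init__()
        self.c1, self.c2, self.k, self.s, self.g = c1, c2, k, s, g
        self.p = autopad(k, p)
        self.act = act
        kh, kw = _khkw(k)
        self.weight = Parameter(_kaiming((c2, c1 // g, kh, kw), c1 // g * kh * kw, _INIT_RNG))
        self.bn = BatchNorm2d(c2)

    def forward(self, x):
        y = T.conv2d(x, self.weight, None, self.s, self.p, self.g)
        y = self.bn(y)
        return ACTS[self.act](y)

    def deployed_param_count(self):
        return self.weight.data.size + self.c2

    def macs(self, ho, wo):
        kh, kw = _khkw(self.k)
        return kh * kw * self.c1 * self.c2 // self.g * ho * wo


class DWConv(Conv):
    """Depthwise Conv block (groups = channels)."""

    def __init__(self, c1, c2, k=3, s=1, act="silu"):
        super().__init__(c1, c2, k, s, g=c1, act=act)


class RawConv(Module):
    """Custom-module convolution: bias-free conv + standalone BN (+act).

    A framework fuse pass does not touch these, so the deployed count
    keeps the BN's gamma/beta (``weights + 2*c2``).
    """

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act="relu6"):
        super().__init__()
        self.c1, self.c2, self.k, self.s, self.g = c1, c2, k, s, g
        self.p = autopad(k, p)
        self.act = act
        kh, kw = _khkw(k)
        self.weight = Parameter(_kaiming((c2, c1 // g, kh, kw), c1 // g * kh * kw, _INIT_RNG))
        self.bn = BatchNorm2d(c2)

    def forward(self, x):
        y = T.conv2d(x, self.weight, None, self.s, self.p, self.g)
        y = self.bn(y)
        return ACTS[self.act](y)

    def macs(self, ho, wo):
        kh, kw = _khkw(self.k)
        return kh * kw * self.c1 * self.c2 // self.g * ho * wo


class Upsample(Module):
    def __init__(self, scale=2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return T.upsample_nearest2d(x, self.scale)


class Concat(Module):
    def __init__(self, axis=1):
        super().__init__()
        self.axis = axis

    def forward(self, xs):
        return T.concat(xs, self.axis)
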