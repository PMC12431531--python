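"""Inverted-residual MBConv block and closed-form convolution cost arithmetic.

The cost functions count multiply–accumulate operations:

* dense convolution:      ``Kh*Kw*Cin*Cout*Hout*Wout``
* depthwise separable:    ``Kh*Kw*Cin*Hout*Wout + Cin*Cout*Hout*Wout``
* their ratio:            ``1/Cout + 1/(Kh*Kw)``

so a 3x3 depthwise separable layer approaches a 9x reduction as the
output width grows.  These identities hold exactly and are the basis of
the model profiler.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .nn import tensor as T
from .nn.modules import Module, PlainConv2d, RawConv


@dataclass
class ConvDims:
    """Dimensions of one convolution layer (all positive integers)."""
    Kh: int
    Kw: int
    Cin: int
    Cout: int
    Hout: int
    Wout: int

    def __post_init__(self):
        for f in ("Kh", "Kw", "Cin", "Cout", "Hout", "Wout"):
            v = getattr(self, f)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{f} must be a positive integer, got {v!r}")


def flops_conv(d: ConvDims) -> int:
    """Multiply–accumulates of a dense convolution."""
    return d.Kh * d.Kw * d.Cin * d.Cout * d.Hout * d.Wout


def flops_dwconv(d: ConvDims) -> int:
    """Multiply–accumulates of a depthwise separable convolution
    (depthwise pass plus 1x1 pointwise fusion)."""
    return d.Kh * d.Kw * d.Cin * d.Hout * d.Wout + d.Cin * d.Cout * d.Hout * d.Wout


def flops_ratio(d: ConvDims) -> Fraction:
    """Exact cost ratio ``flops_dwconv / flops_conv = 1/Cout + 1/(Kh*Kw)``."""
    return Fraction(1, d.Cout) + Fraction(1, d.Kh * d.Kw)


@dataclass
class MBConvSpec:
    """Configuration of one inverted-residual block.

    ``expansion_t`` widens the pointwise expansion; the skip connection
    is active exactly when ``c_in == c_out`` and ``stride == 1``.
    """
    c_in: int
    c_out: int
    expansion_t: int = 4
    kernel: int = 3
    stride: int = 1
    se_ratio: float = 0.25
    se_width: int | None = None     # explicit squeeze width overrides se_ratio

    def __post_init__(self):
        if self.kernel % 2 == 0:
            raise ValueError("depthwise kernel must be odd")
        if not (0 < self.se_ratio <= 1):
            raise ValueError("se_ratio must be in (0, 1]")
        if self.expansion_t < 1:
            raise ValueError("expansion ratio must be >= 1")

    @property
    def hidden(self) -> int:
        return self.expansion_t * self.c_in

    @property
    def squeeze(self) -> int:
        if self.se_width is not None:
            return self.se_width
        return max(1, int(self.c_in * self.se_ratio))

    @property
    def has_skip(self) -> bool:
        return self.c_in == self.c_out and self.stride == 1


class SqueezeExcite(Module):
    """Global-pool -> reduce -> ReLU6 -> expand -> sigmoid channel gate."""

    def __init__(self, channels: int, squeeze: int):
        super().__init__()
        self.reduce = PlainConv2d(channels, squeeze, 1, bias=True)
        self.expand = PlainConv2d(squeeze, channels, 1, bias=True)

    def forward(self, x):
        s = x.mean(axis=(2, 3), keepdims=True)
        s = T.sigmoid(self.expand(T.relu6(self.reduce(s))))
        return x * s


class MBConv(Module):
    """Expansion -> depthwise -> squeeze-excitation -> projection (+skip).

    Convolutions are bias-free with their own batch norm (these blocks
    are opaque to a framework fuse pass, so the deployed count keeps the
    BN affine pairs).  ReLU6 activations throughout, as used in the
    detection-head context.
    """

    def __init__(self, spec: MBConvSpec):
        super().__init__()
        self.spec = spec
        h = spec.hidden
        self.expand = (RawConv(spec.c_in, h, 1, act="relu6")
                       if h != spec.c_in else None)
        self.dw = RawConv(h, h, spec.kernel, s=spec.stride, g=h, act="relu6")
        self.se = SqueezeExcite(h, spec.squeeze)
        self.project = RawConv(h, spec.c_out, 1, act=None)

    def forward(self, x):
        if x.shape[1] != self.spec.c_in:
            raise ValueError(f"expected {self.spec.c_in} channels, got {x.shape[1]}")
        y = self.expand(x) if self.expand is not None else x
        y = self.dw(y)
        y = self.se(y)
        y = self.project(y)
        return x + y if self.spec.has_skip else y

    def profile(self, h, w):
        ho, wo = h // self.spec.stride, w // self.spec.stride
        macs = 0
        if self.expand is not None:
            macs += self.expand.macs(h, w)
        macs += self.dw.macs(ho, wo)
        hid, s = self.spec.hidden, self.spec.squeeze
        macs += hid * s + s * hid          # SE on pooled vector
        macs += self.project.macs(ho, wo)
        return macs


def mbconv_forward(x: np.ndarray, spec: MBConvSpec, module: MBConv | None = None) -> np.ndarray:
    """Run one MBConv block over a plain array (evaluation mode)."""
    if module is None:
        module = MBConv(spec)
    module.eval()
    with T.no_grad():
        return module(T.Tensor(np.asarray(x, dtype=np.float32))).data
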