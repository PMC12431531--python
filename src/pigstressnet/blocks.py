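"""Backbone/neck building blocks of the YOLOv12-style skeleton.

The nano-scale detector is assembled from three block families:

* ``C3k2`` — cross-stage partial blocks with small residual bottlenecks,
  used early in the backbone and at the deepest neck stage;
* ``A2C2f`` — cross-stage blocks whose inner mixer is either area
  attention (``ABlock`` pairs, backbone) or a ``C3k`` convolutional
  mixer (neck);
* area attention (``AAttn``) — multi-head self-attention computed inside
  rectangular areas of the feature map, with a depthwise positional
  encoding.

Every block preserves its contract shape and exposes ``profile(h, w)``
returning the convolution multiply–accumulate count used by the FLOPs
profiler (attention tensor products are deliberately excluded there;
see the profiling convention in the methods note).
"""

from __future__ import annotations

import numpy as np

from .nn import tensor as T
from .nn.modules import Conv, Module, ModuleList, Sequential


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, k=(3, 3), e=0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, k[0], 1)
        self.cv2 = Conv(c_, c2, k[1], 1)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def profile(self, h, w):
        return self.cv1.macs(h, w) + self.cv2.macs(h, w)


class C3k(Module):
    """CSP block with three 1x1 convs around ``n`` full-width bottlenecks."""

    def __init__(self, c1, c2, n=2, shortcut=True, e=0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c1, c_, 1, 1)
        self.cv3 = Conv(2 * c_, c2, 1, 1)
        self.m = ModuleList(Bottleneck(c_, c_, shortcut, e=1.0) for _ in range(n))

    def forward(self, x):
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(T.concat([y, self.cv2(x)], 1))

    def profile(self, h, w):
        macs = self.cv1.macs(h, w) + self.cv2.macs(h, w) + self.cv3.macs(h, w)
        return macs + sum(b.profile(h, w) for b in self.m)


class C3k2(Module):
    """Two-way CSP block; inner mixers are bottlenecks or nested C3k."""

    def __init__(self, c1, c2, n=1, c3k=False, e=0.5, shortcut=True):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, 1)
        self.cv2 = Conv((2 + n) * self.c, c2, 1, 1)
        self.m = ModuleList(
            C3k(self.c, self.c, 2, shortcut) if c3k
            else Bottleneck(self.c, self.c, shortcut, e=0.5)
            for _ in range(n)
        )

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c:]
        ys = [a, b]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(T.concat(ys, 1))

    def profile(self, h, w):
        macs = self.cv1.macs(h, w) + self.cv2.macs(h, w)
        return macs + sum(m.profile(h, w) for m in self.m)


class AAttn(Module):
    """Area attention: softmax attention within ``area`` horizontal bands.

    The map is flattened to N tokens, split into ``area`` equal groups of
    consecutive tokens, and multi-head attention runs independently per
    group.  A depthwise 7x7 convolution of V provides the positional
    encoding.
    """

    def __init__(self, dim, num_heads, area=1):
        super().__init__()
        self.dim, self.num_heads, self.area = dim, num_heads, area
        self.head_dim = dim // num_heads
        self.qkv = Conv(dim, dim * 3, 1, act=None)
        self.proj = Conv(dim, dim, 1, act=None)
        self.pe = Conv(dim, dim, 7, 1, 3, g=dim, act=None)

    def forward(self, x):
        n, c, h, w = x.shape
        qkv = self.qkv(x)                                    # (n, 3c, h, w)
        v_map = qkv[:, 2 * c:]
        pe = self.pe(v_map)
        N = h * w
        a = self.area if N % self.area == 0 else 1
        toks = qkv.reshape(n, 3, self.num_heads, self.head_dim, N)
        toks = toks.transpose(1, 0, 2, 4, 3)                 # (3, n, heads, N, hd)
        q, k, v = toks[0], toks[1], toks[2]
        if a > 1:
            na = N // a
            q = q.reshape(n, self.num_heads, a, na, self.head_dim)
            k = k.reshape(n, self.num_heads, a, na, self.head_dim)
            v = v.reshape(n, self.num_heads, a, na, self.head_dim)
        scale = 1.0 / np.sqrt(self.head_dim)
        attn = T.softmax(T.matmul(q, k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) * scale, axis=-1)
        out = T.matmul(attn, v)
        if a > 1:
            out = out.reshape(n, self.num_heads, N, self.head_dim)
        out = out.transpose(0, 1, 3, 2).reshape(n, c, h, w)
        return self.proj(out + pe)

    def profile(self, h, w):
        return self.qkv.macs(h, w) + self.proj.macs(h, w) + self.pe.macs(h, w)


class ABlock(Module):
    """Area-attention transformer block with a 2x convolutional MLP."""

    def __init__(self, dim, num_heads, mlp_ratio=2.0, area=1):
        super().__init__()
        self.attn = AAttn(dim, num_heads, area)
        hidden = int(dim * mlp_ratio)
        self.mlp = Sequential(Conv(dim, hidden, 1), Conv(hidden, dim, 1, act=None))

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.mlp(x)

    def profile(self, h, w):
        return self.attn.profile(h, w) + sum(c.macs(h, w) for c in self.mlp)


class A2C2f(Module):
    """Cross-stage block: attention mixers in the backbone (``a2=True``),
    ``C3k`` mixers in the neck."""

    def __init__(self, c1, c2, n=1, a2=True, area=1, shortcut=True):
        super().__init__()
        c_ = int(c2 * 0.5)
        assert not a2 or c_ % 32 == 0, "attention width must be a multiple of 32"
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv((1 + n) * c_, c2, 1)
        self.m = ModuleList(
            Sequential(*(ABlock(c_, c_ // 32, 2.0, area) for _ in range(2))) if a2
            else C3k(c_, c_, 2, shortcut)
            for _ in range(n)
        )

    def forward(self, x):
        ys = [self.cv1(x)]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(T.concat(ys, 1))

    def profile(self, h, w):
        macs = self.cv1.macs(h, w) + self.cv2.macs(h, w)
        for m in self.m:
            if isinstance(m, Sequential):
                macs += sum(b.profile(h, w) for b in m)
            else:
                macs += m.profile(h, w)
        return macs
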