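"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based autograd engine: each :class:`Tensor` wraps a
``float32`` numpy array and remembers how it was produced, so a single
:meth:`Tensor.backward` call propagates gradients through the whole
graph.  Only the operations needed by the detector are implemented
(dense/depthwise convolution, batch normalisation, batched matmul, the
usual pointwise nonlinearities and shape ops).  Heavy lifting is done by
BLAS through ``np.matmul``/``einsum``; dense convolutions lower onto
GEMM via a block-copy im2col (patches are re-derived in the backward
pass instead of cached, which keeps training memory flat), and
depthwise convolutions use direct shift-and-accumulate.
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # keep numpy from hijacking `ndarray <op> Tensor`: returning
    # NotImplemented makes python fall back to our reflected operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        elif data.dtype != np.float32:
            data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad and _grad_enabled
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.accumulate(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
                # free interior gradients/graph once consumed
                if t is not self:
                    t._backward = None
                    t.grad = None
                    t._parents = ()

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, pow_(other, -1.0))
        return mul(self, 1.0 / other)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):
        return f"Tensor{self.data.shape}"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward):
    req = _grad_enabled and any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req,
                  parents=tuple(p for p in parents if p.requires_grad),
                  backward=backward if req else None)


# -- elementwise -----------------------------------------------------------

def add(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def pow_(a, p: float):
    a = astensor(a)
    out_data = a.data ** p

    def backward(g):
        a.accumulate(_unbroadcast(g * p * a.data ** (p - 1.0), a.data.shape))

    return _make(out_data, (a,), backward)


def _expit(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -80.0, 80.0)))


def sigmoid(a):
    a = astensor(a)
    s = _expit(a.data)

    def backward(g):
        a.accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def silu(a):
    a = astensor(a)
    out_data = a.data * _expit(a.data)

    def backward(g):
        s = _expit(a.data)
        a.accumulate(g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(out_data, (a,), backward)


def relu6(a):
    a = astensor(a)
    out_data = np.clip(a.data, 0.0, 6.0)

    def backward(g):
        mask = (a.data > 0.0) & (a.data < 6.0)
        a.accumulate(g * mask)

    return _make(out_data, (a,), backward)


def relu(a):
    a = astensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        a.accumulate(g * (a.data > 0.0))

    return _make(out_data, (a,), backward)


def gelu(a):
    # tanh approximation; exactness is irrelevant at these scales
    a = astensor(a)
    c = np.float32(np.sqrt(2.0 / np.pi))
    t = np.tanh(c * (a.data + 0.044715 * a.data ** 3))
    out_data = 0.5 * a.data * (1.0 + t)

    def backward(g):
        dt = (1.0 - t ** 2) * c * (1.0 + 3 * 0.044715 * a.data ** 2)
        a.accumulate(g * (0.5 * (1.0 + t) + 0.5 * a.data * dt))

    return _make(out_data, (a,), backward)


def exp(a):
    a = astensor(a)
    e = np.exp(a.data)

    def backward(g):
        a.accumulate(g * e)

    return _make(e, (a,), backward)


def log(a):
    a = astensor(a)

    def backward(g):
        a.accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def clip(a, lo, hi):
    a = astensor(a)
    out_data = np.clip(a.data, lo, hi)

    def backward(g):
        a.accumulate(g * ((a.data > lo) & (a.data < hi)))

    return _make(out_data, (a,), backward)


def softmax(a, axis=-1):
    a = astensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a.accumulate(s * (g - dot))

    return _make(s, (a,), backward)


# -- reductions / shape ----------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            grad = np.broadcast_to(g, a.data.shape)
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            grad = np.broadcast_to(g, a.data.shape)
        a.accumulate(np.ascontiguousarray(grad))

    return _make(out_data, (a,), backward)


def mean(a, axis=None, keepdims=False):
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in axes]))
    return mul(sum_(a, axis, keepdims), 1.0 / n)


def reshape(a, shape):
    a = astensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a.accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes):
    a = astensor(a)
    out_data = np.ascontiguousarray(a.data.transpose(axes))
    inv = np.argsort(axes)

    def backward(g):
        a.accumulate(np.ascontiguousarray(g.transpose(inv)))

    return _make(out_data, (a,), backward)


def getitem(a, idx):
    a = astensor(a)
    out_data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a.accumulate(full)

    return _make(np.ascontiguousarray(out_data), (a,), backward)


def concat(tensors, axis=1):
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(np.ascontiguousarray(g[tuple(sl)]))

    return _make(out_data, tuple(tensors), backward)


def matmul(a, b):
    """Batched matrix product with broadcasting over leading axes."""
    a, b = astensor(a), astensor(b)
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a.accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b.accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def upsample_nearest2d(a, scale=2):
    a = astensor(a)
    out_data = a.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        n, c, h, w = a.data.shape
        gg = g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
        a.accumulate(gg)

    return _make(out_data, (a,), backward)


# -- convolution -----------------------------------------------------------

def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def _im2col(x: np.ndarray, k, stride: int, pad):
    kh, kw = _pair(k)
    ph, pw = _pair(pad)
    n, c, h, w = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    # one large strided block copy per kernel tap (cache-friendly)
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, k, stride: int, pad, ho: int, wo: int):
    kh, kw = _pair(k)
    ph, pw = _pair(pad)
    n, c, h, w = x_shape
    hp, wp = h + 2 * ph, w + 2 * pw
    out = np.zeros((n, c, hp, wp), dtype=np.float32)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    if ph or pw:
        out = out[:, :, ph:hp - ph, pw:wp - pw]
    return np.ascontiguousarray(out)


def conv2d(x, weight, bias=None, stride=1, padding=0, groups=1):
    """2-D cross-correlation.  ``groups`` must be 1 or the channel count
    (depthwise); those are the only forms the detector uses."""
    x, weight = astensor(x), astensor(weight)
    if bias is not None:
        bias = astensor(bias)
    n, c1, h, w = x.data.shape
    c2, cg, kh, kw = weight.data.shape
    k = (kh, kw)

    if groups == 1:
        ph, pw = _pair(padding)
        wmat = weight.data.reshape(c2, c1 * kh * kw)
        if (kh, kw) == (1, 1) and stride == 1 and ph == 0 and pw == 0:
            # pointwise: pure GEMM on a view, nothing cached
            xm = x.data.reshape(n, c1, h * w)
            out = np.matmul(wmat, xm).reshape(n, c2, h, w)
            ho, wo = h, w

            def backward(g):
                gm = g.reshape(n, c2, h * w)
                if weight.requires_grad:
                    gw = np.einsum("ncl,nkl->ck", gm, x.data.reshape(n, c1, h * w),
                                   optimize=True)
                    weight.accumulate(gw.reshape(weight.data.shape))
                if x.requires_grad:
                    x.accumulate(np.matmul(wmat.T, gm).reshape(x.data.shape))
                if bias is not None and bias.requires_grad:
                    bias.accumulate(g.sum(axis=(0, 2, 3)))
        else:
            cols, ho, wo = _im2col(x.data, k, stride, padding)
            out = np.matmul(wmat, cols).reshape(n, c2, ho, wo)
            cols = None   # re-derived in backward; do not hold the buffer

            def backward(g):
                gm = g.reshape(n, c2, ho * wo)
                if weight.requires_grad:
                    cols2, _, _ = _im2col(x.data, k, stride, padding)
                    gw = np.einsum("ncl,nkl->ck", gm, cols2, optimize=True)
                    weight.accumulate(gw.reshape(weight.data.shape))
                    del cols2
                if x.requires_grad:
                    gcols = np.matmul(wmat.T, gm)
                    x.accumulate(_col2im(gcols, x.data.shape, k, stride, padding, ho, wo))
                if bias is not None and bias.requires_grad:
                    bias.accumulate(g.sum(axis=(0, 2, 3)))

    elif groups == c1 and c2 == c1:
        # depthwise: shift-and-accumulate, no im2col needed
        ph, pw = _pair(padding)
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
        ho = (xp.shape[2] - kh) // stride + 1
        wo = (xp.shape[3] - kw) // stride + 1
        wv = weight.data.reshape(c1, kh, kw)
        out = np.zeros((n, c1, ho, wo), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                out += xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] \
                    * wv[:, i, j].reshape(1, c1, 1, 1)

        def backward(g):
            if weight.requires_grad:
                gw = np.empty((c1, kh, kw), dtype=np.float32)
                for i in range(kh):
                    for j in range(kw):
                        patch = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
                        gw[:, i, j] = (g * patch).sum(axis=(0, 2, 3))
                weight.accumulate(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                            g * wv[:, i, j].reshape(1, c1, 1, 1)
                hpp, wpp = gxp.shape[2], gxp.shape[3]
                gx = gxp[:, :, ph:hpp - ph, pw:wpp - pw] if (ph or pw) else gxp
                x.accumulate(np.ascontiguousarray(gx))
            if bias is not None and bias.requires_grad:
                bias.accumulate(g.sum(axis=(0, 2, 3)))

    else:  # pragma: no cover - not used by any model in the package
        raise NotImplementedError("only dense or depthwise convolutions are supported")

    if bias is not None:
        out = out + bias.data.reshape(1, c2, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    return _make(out, parents, backward)


def batch_norm(x, gamma, beta, running_mean, running_var,
               training: bool, momentum: float = 0.1, eps: float = 1e-5,
               axis=(0, 2, 3)):
    """Batch normalisation over ``axis`` with running-statistics update.

    ``gamma``/``beta`` broadcast against the normalised input; in training
    mode the mini-batch moments are used and the running buffers updated
    in place.
    """
    x = astensor(x)
    shape = [1] * x.ndim
    for i in range(x.ndim):
        if i not in axis:
            shape[i] = x.data.shape[i]
    if training:
        mu = x.data.mean(axis=axis, keepdims=True)
        var = x.data.var(axis=axis, keepdims=True)
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu.reshape(running_mean.shape)
        n = x.data.size / mu.size
        unbiased = var.reshape(running_var.shape) * (n / max(n - 1.0, 1.0))
        running_var *= (1.0 - momentum)
        running_var += momentum * unbiased
    else:
        mu = running_mean.reshape(shape)
        var = running_var.reshape(shape)
    inv = 1.0 / np.sqrt(var + eps)
    g2 = gamma.data.reshape(shape)
    out = (x.data - mu) * (inv * g2) + beta.data.reshape(shape)

    def backward(g):
        xhat = (x.data - mu) * inv
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=axis).reshape(gamma.data.shape))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=axis).reshape(beta.data.shape))
        if x.requires_grad:
            if training:
                m = x.data.size / mu.size
                gx = g * g2
                gmu = gx.sum(axis=axis, keepdims=True)
                gdot = (gx * xhat).sum(axis=axis, keepdims=True)
                x.accumulate(inv * (gx - gmu / m - xhat * gdot / m))
            else:
                x.accumulate(g * g2 * inv)

    return _make(out, (x, gamma, beta), backward)


def maximum(a, b):
    a, b = astensor(a), astensor(b)
    out_data = np.maximum(a.data, b.data)

    def backward(g):
        amask = a.data >= b.data
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * amask, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * ~amask, b.data.shape))

    return _make(out_data, (a, b), backward)


def minimum(a, b):
    a, b = astensor(a), astensor(b)
    out_data = np.minimum(a.data, b.data)

    def backward(g):
        amask = a.data <= b.data
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * amask, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * ~amask, b.data.shape))

    return _make(out_data, (a, b), backward)


def stack(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(np.ascontiguousarray(gp))

    return _make(out_data, tuple(tensors), backward)
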