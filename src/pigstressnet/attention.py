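"""Normalization-based attention (NAM) and the rectangular self-calibration module (RCM).

NAM reuses batch-normalisation scale factors as importance weights: the
per-channel BN scales :math:`\\gamma` are normalised to a probability
vector :math:`W_\\gamma` and the gate is
``sigmoid(W_gamma * BN(x))`` applied multiplicatively to the input.  The
spatial submodule does the same over pixel positions ("pixel
normalisation") with scales :math:`\\lambda`.  An L1 penalty on
:math:`\\gamma` and :math:`\\lambda` (weighted by ``p``) is added to the
training loss to sparsify unimportant channels/pixels.

The RCM captures axial global context: horizontal and vertical mean
pooling produce two axial vectors whose broadcast sum forms a
rectangular attention map; two large-kernel strip convolutions (1xk and
kx1, depthwise) reshape that rectangle toward the foreground ("shape
self-calibration"); the sigmoid-gated attention is multiplied into a
3x3-depthwise-refined copy of the input, and a BN + MLP refinement with
a residual connection closes the block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import tensor as T
from .nn.modules import (BatchNorm2d, Module, Parameter, PlainConv2d)


# ---------------------------------------------------------------------------
# functional layer (stateless API over plain arrays)
# ---------------------------------------------------------------------------

@dataclass
class BatchNormState:
    """Explicit batch-norm statistics and affine parameters.

    All vectors have length equal to the channel count; ``epsilon`` must
    be positive and ``sigma2_B`` non-negative.
    """
    mu_B: np.ndarray
    sigma2_B: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    epsilon: float = 1e-5

    def __post_init__(self):
        self.mu_B = np.asarray(self.mu_B, dtype=np.float64)
        self.sigma2_B = np.asarray(self.sigma2_B, dtype=np.float64)
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if np.any(self.sigma2_B < 0):
            raise ValueError("variances must be non-negative")
        n = len(self.gamma)
        if not (len(self.beta) == len(self.mu_B) == len(self.sigma2_B) == n):
            raise ValueError("per-channel vectors must share one length")


def batch_norm(x: np.ndarray, state: BatchNormState) -> np.ndarray:
    """Channel-wise affine standardisation ``gamma*(x-mu)/sqrt(var+eps)+beta``.

    ``x`` is (N, C, H, W) or any array whose second axis is the channel
    axis; shape is preserved.
    """
    x = np.asarray(x, dtype=np.float64)
    c = x.shape[1]
    if c != len(state.gamma):
        raise ValueError(f"channel mismatch: x has {c}, state has {len(state.gamma)}")
    shape = (1, c) + (1,) * (x.ndim - 2)
    mu = state.mu_B.reshape(shape)
    var = state.sigma2_B.reshape(shape)
    return (state.gamma.reshape(shape) * (x - mu) / np.sqrt(var + state.epsilon)
            + state.beta.reshape(shape))


def nam_channel_weights(gamma: np.ndarray, zero_policy: str = "error") -> np.ndarray:
    """Normalised channel importance ``|gamma_i| / sum_j |gamma_j|``.

    Negative BN scales carry no meaningful "importance" sign, so the
    absolute-value convention is used; the result is a probability
    vector.  ``zero_policy`` controls the degenerate all-zero case:
    ``"error"`` raises, ``"uniform"`` falls back to ``1/C``.
    """
    gamma = np.asarray(gamma, dtype=np.float64)
    if gamma.size == 0:
        raise ValueError("need at least one channel")
    total = np.abs(gamma).sum()
    if total == 0:
        if zero_policy == "uniform":
            return np.full(gamma.shape, 1.0 / gamma.size)
        raise ValueError("all scales are zero; weights are degenerate")
    return np.abs(gamma) / total


def nam_regularizer(gamma, lambda_=(), p: float = 1e-4) -> float:
    """Sparsity penalty ``p*sum|gamma| + p*sum|lambda|`` added to the loss."""
    if p < 0:
        raise ValueError("balance factor p must be non-negative")
    g = float(np.abs(np.asarray(gamma, dtype=np.float64)).sum()) if len(np.atleast_1d(gamma)) else 0.0
    l = float(np.abs(np.asarray(lambda_, dtype=np.float64)).sum()) if len(np.atleast_1d(lambda_)) else 0.0
    return p * g + p * l


@dataclass
class NamChannelState:
    bn: BatchNormState

    @property
    def weight_W_gamma(self) -> np.ndarray:
        return nam_channel_weights(self.bn.gamma)


@dataclass
class NamSpatialState:
    bn_s: BatchNormState   # one "channel" per spatial position, scale lambda

    @property
    def weight_W_lambda(self) -> np.ndarray:
        return nam_channel_weights(self.bn_s.gamma)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def nam_channel_forward(f1: np.ndarray, state: NamChannelState) -> np.ndarray:
    """Gate ``F1 * sigmoid(W_gamma * BN(F1))`` with per-channel weights."""
    f1 = np.asarray(f1, dtype=np.float64)
    if np.isnan(f1).any():
        raise ValueError("NaN in input feature map")
    bn = batch_norm(f1, state.bn)
    w = state.weight_W_gamma.reshape((1, -1) + (1,) * (f1.ndim - 2))
    return f1 * _sigmoid(w * bn)


def nam_spatial_forward(f2: np.ndarray, state: NamSpatialState) -> np.ndarray:
    """Pixel-normalisation gate: as the channel form, but over positions.

    ``f2`` is (N, C, H, W); each of the H*W positions has its own scale
    ``lambda`` and shift, normalised over the batch and channel axes.
    """
    f2 = np.asarray(f2, dtype=np.float64)
    if np.isnan(f2).any():
        raise ValueError("NaN in input feature map")
    n, c, h, w = f2.shape
    flat = f2.reshape(n * c, h * w).T[None, ...]   # (1, HW, N*C): positions as channels
    bn = batch_norm(flat, state.bn_s)[0]           # (HW, N*C)
    wl = nam_channel_weights(state.bn_s.gamma).reshape(-1, 1)
    gated = flat[0] * _sigmoid(wl * bn)
    return gated.T.reshape(n, c, h, w)


# ---------------------------------------------------------------------------
# trainable modules
# ---------------------------------------------------------------------------

class NAMChannel(Module):
    """Channel attention submodule: standalone BN whose scales gate the input."""

    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels
        self.bn = BatchNorm2d(channels)

    def forward(self, x):
        bn = self.bn(x)
        g = self.bn.gamma.data
        total = np.abs(g).sum()
        w = (np.abs(g) / total if total > 0 else np.full_like(g, 1.0 / g.size))
        gate = T.sigmoid(bn * w.reshape(1, -1, 1, 1))
        return x * gate

    def profile(self, h, w):
        return 0  # elementwise only

    @property
    def gamma(self):
        return self.bn.gamma


class NAMSpatial(Module):
    """Pixel-normalisation attention for a fixed spatial size."""

    def __init__(self, height: int, width: int):
        super().__init__()
        self.height, self.width = height, width
        n = height * width
        self.lam = Parameter(np.ones(n))
        self.beta = Parameter(np.zeros(n))
        self.running_mean = np.zeros(n, dtype=np.float32)
        self.running_var = np.ones(n, dtype=np.float32)

    def forward(self, x):
        n, c, h, w = x.shape
        flat = x.reshape(n * c, h * w).transpose(1, 0).reshape(1, h * w, n * c)
        bn = T.batch_norm(flat, self.lam, self.beta, self.running_mean,
                          self.running_var, self.training, axis=(0, 2))
        lam = self.lam.data
        total = np.abs(lam).sum()
        wl = (np.abs(lam) / total if total > 0 else np.full_like(lam, 1.0 / lam.size))
        gate = T.sigmoid(bn * wl.reshape(1, -1, 1))
        gated = flat * gate
        return gated.reshape(h * w, n, c).transpose(1, 2, 0).reshape(n, c, h, w)

    def profile(self, h, w):
        return 0


@dataclass
class RcmState:
    """Hyperparameters of the rectangular self-calibration module."""
    channels: int
    strip_kernel: int = 11
    mlp_expansion: int = 2
    dw_kernel: int = 3

    def __post_init__(self):
        if self.strip_kernel < 3 or self.strip_kernel % 2 == 0:
            raise ValueError("strip kernel must be odd and >= 3")


class RCM(Module):
    """Rectangular self-calibration block (axial pooling + strip calibration).

    The default hyperparameters (strip kernel 11, MLP expansion 2,
    depthwise 3x3) are the calibrated configuration recorded in the
    package config; at 64 channels the block carries exactly 19,072
    deployed parameters.
    """

    def __init__(self, channels: int, strip_kernel: int = 11, mlp_expansion: int = 2):
        super().__init__()
        self.state = RcmState(channels, strip_kernel, mlp_expansion)
        c, k = channels, strip_kernel
        self.dwconv_hw = PlainConv2d(c, c, 3, g=c, bias=True)
        self.strip_h = PlainConv2d(c, c, (1, k), g=c, bias=True)
        self.strip_bn = BatchNorm2d(c)
        self.strip_v = PlainConv2d(c, c, (k, 1), g=c, bias=True)
        self.norm = BatchNorm2d(c)
        hidden = mlp_expansion * c
        self.fc1 = PlainConv2d(c, hidden, 1, bias=True)
        self.fc2 = PlainConv2d(hidden, c, 1, bias=True)
        self.gamma = Parameter(np.full(c, 1e-6))

    def forward(self, x):
        n, c, h, w = x.shape
        if h < 1 or w < 1:
            raise ValueError("spatial dims must be at least 1")
        # (a) axial pooling -> (b) rectangular attention region
        x_h = x.mean(axis=3, keepdims=True)     # (n, c, h, 1) vertical axial vector
        x_w = x.mean(axis=2, keepdims=True)     # (n, c, 1, w) horizontal axial vector
        rect = x_h + x_w
        # (c) shape self-calibration by large-kernel strip convolutions
        att = self.strip_v(T.relu(self.strip_bn(self.strip_h(rect))))
        # (d) sigmoid gate, (e) fuse with locally refined input
        att = T.sigmoid(att)
        loc = self.dwconv_hw(x)
        fused = att * loc
        # (f) BN + MLP refinement, (g) residual
        y = self.fc2(T.gelu(self.fc1(self.norm(fused))))
        return x + y * self.gamma.reshape(1, c, 1, 1)

    def profile(self, h, w):
        k = self.state.strip_kernel
        c = self.state.channels
        macs = self.dwconv_hw.macs(h, w)
        macs += self.strip_h.macs(h, w) + self.strip_v.macs(h, w)
        macs += self.fc1.macs(h, w) + self.fc2.macs(h, w)
        return macs


def rcm_forward(x: np.ndarray, state: RcmState, module: RCM | None = None) -> np.ndarray:
    """Run an RCM block over ``x`` (plain-array convenience wrapper)."""
    if module is None:
        module = RCM(state.channels, state.strip_kernel, state.mlp_expansion)
    module.eval()
    with T.no_grad():
        return module(T.Tensor(np.asarray(x, dtype=np.float32))).data
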