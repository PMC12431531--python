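"""Bounding-box overlap measures and regression losses.

Boxes are axis-aligned with corner coordinates ``(x1, y1, x2, y2)``
(top-left origin, ``x1 < x2``, ``y1 < y2``).  Three measures are
provided:

* ``iou`` — intersection over union;
* ``ciou`` — IoU minus a centre-distance penalty (normalised by the
  enclosing-box diagonal) and an aspect-ratio term
  ``m = (4/pi^2) * (arctan(wg/hg) - arctan(w/h))^2`` weighted by
  ``alpha = m / (1 - IoU + m)``;
* ``mpdiou`` — IoU minus the squared distances between the two top-left
  corners and the two bottom-right corners, each normalised by the
  squared image diagonal ``w^2 + h^2``.

``mpdiou`` equals 1 only for identical boxes and is bounded above by the
IoU, so its loss ``1 - MPDIoU`` is zero exactly at a perfect match.  All
functions accept scalars, :class:`Box` instances, or (..., 4) arrays and
are vectorised; ``*_loss_grad`` returns the analytic gradient with
respect to the predicted corners (used by the recovery tests and usable
for plain gradient descent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import tensor as T


@dataclass(frozen=True)
class Box:
    """Axis-aligned box with strictly positive area."""
    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        vals = (self.x1, self.y1, self.x2, self.y2)
        if not all(np.isfinite(vals)):
            raise ValueError("box coordinates must be finite")
        if self.x2 <= self.x1 or self.y2 <= self.y1:
            raise ValueError("box must have positive area (x1<x2, y1<y2)")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)


@dataclass(frozen=True)
class ImageExtent:
    """Image width/height normalising the corner distances in MPDIoU."""
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("image extent must be positive")


def _coerce(b) -> np.ndarray:
    if isinstance(b, Box):
        return b.as_array()
    a = np.asarray(b, dtype=np.float64)
    if a.shape[-1] != 4:
        raise ValueError("boxes must have 4 coordinates on the last axis")
    if not np.isfinite(a).all():
        raise ValueError("box coordinates must be finite")
    if np.any(a[..., 2] <= a[..., 0]) or np.any(a[..., 3] <= a[..., 1]):
        raise ValueError("boxes must have positive area")
    return a


def iou(a, b):
    """Intersection over union, in [0, 1]; 0 for disjoint boxes."""
    A, B = _coerce(a), _coerce(b)
    ix = np.minimum(A[..., 2], B[..., 2]) - np.maximum(A[..., 0], B[..., 0])
    iy = np.minimum(A[..., 3], B[..., 3]) - np.maximum(A[..., 1], B[..., 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (A[..., 2] - A[..., 0]) * (A[..., 3] - A[..., 1])
    area_b = (B[..., 2] - B[..., 0]) * (B[..., 3] - B[..., 1])
    out = inter / (area_a + area_b - inter)
    return float(out) if out.ndim == 0 else out


def ciou(p, pgt):
    """Complete IoU: IoU − ρ²/c² − α·m (centre distance + aspect term)."""
    P, G = _coerce(p), _coerce(pgt)
    base = iou(P, G)
    base = np.asarray(base, dtype=np.float64)
    cx_p, cy_p = (P[..., 0] + P[..., 2]) / 2, (P[..., 1] + P[..., 3]) / 2
    cx_g, cy_g = (G[..., 0] + G[..., 2]) / 2, (G[..., 1] + G[..., 3]) / 2
    rho2 = (cx_p - cx_g) ** 2 + (cy_p - cy_g) ** 2
    ex1 = np.minimum(P[..., 0], G[..., 0])
    ey1 = np.minimum(P[..., 1], G[..., 1])
    ex2 = np.maximum(P[..., 2], G[..., 2])
    ey2 = np.maximum(P[..., 3], G[..., 3])
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2
    if np.any(c2 <= 0):
        raise ValueError("degenerate enclosing box")
    wp, hp = P[..., 2] - P[..., 0], P[..., 3] - P[..., 1]
    wg, hg = G[..., 2] - G[..., 0], G[..., 3] - G[..., 1]
    m = (4.0 / np.pi ** 2) * (np.arctan(wg / hg) - np.arctan(wp / hp)) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(m > 0, m / (1.0 - base + m), 0.0)
    out = base - rho2 / c2 - alpha * m
    return float(out) if out.ndim == 0 else out


def mpdiou(p, pgt, ext: ImageExtent):
    """Minimum-point-distance IoU: IoU − d1²/(w²+h²) − d2²/(w²+h²)."""
    P, G = _coerce(p), _coerce(pgt)
    base = np.asarray(iou(P, G), dtype=np.float64)
    denom = ext.w ** 2 + ext.h ** 2
    d1 = (P[..., 0] - G[..., 0]) ** 2 + (P[..., 1] - G[..., 1]) ** 2
    d2 = (P[..., 2] - G[..., 2]) ** 2 + (P[..., 3] - G[..., 3]) ** 2
    out = base - d1 / denom - d2 / denom
    return float(out) if out.ndim == 0 else out


def mpdiou_loss(p, pgt, ext: ImageExtent):
    """``1 − MPDIoU``; non-negative, zero only for identical boxes."""
    out = 1.0 - np.asarray(mpdiou(p, pgt, ext), dtype=np.float64)
    return float(out) if out.ndim == 0 else out


def mpdiou_loss_grad(p, pgt, ext: ImageExtent) -> np.ndarray:
    """Analytic d(loss)/d(pred corners), shape (..., 4).

    The IoU term is piecewise smooth; at ties the subgradient of the
    active branch is returned (the same convention autodiff uses).
    """
    P, G = _coerce(p), _coerce(pgt)
    P = np.atleast_2d(P)
    G = np.broadcast_to(np.atleast_2d(G), P.shape)
    x1, y1, x2, y2 = P[..., 0], P[..., 1], P[..., 2], P[..., 3]
    g1, h1, g2, h2 = G[..., 0], G[..., 1], G[..., 2], G[..., 3]
    ix1, iy1 = np.maximum(x1, g1), np.maximum(y1, h1)
    ix2, iy2 = np.minimum(x2, g2), np.minimum(y2, h2)
    iw, ih = np.clip(ix2 - ix1, 0, None), np.clip(iy2 - iy1, 0, None)
    inter = iw * ih
    area_p = (x2 - x1) * (y2 - y1)
    area_g = (g2 - g1) * (h2 - h1)
    union = area_p + area_g - inter
    # d inter / d corners (active only when that corner bounds the overlap)
    di = np.zeros_like(P)
    pos = (iw > 0) & (ih > 0)
    di[..., 0] = np.where(pos & (x1 >= g1), -ih, 0.0)
    di[..., 1] = np.where(pos & (y1 >= h1), -iw, 0.0)
    di[..., 2] = np.where(pos & (x2 <= g2), ih, 0.0)
    di[..., 3] = np.where(pos & (y2 <= h2), iw, 0.0)
    da = np.stack([-(y2 - y1), -(x2 - x1), (y2 - y1), (x2 - x1)], axis=-1)
    # d IoU = (di*union - inter*(da - di)) / union^2
    diou = (di * union[..., None] - inter[..., None] * (da - di)) / union[..., None] ** 2
    denom = ext.w ** 2 + ext.h ** 2
    dpen = np.stack([2 * (x1 - g1), 2 * (y1 - h1),
                     2 * (x2 - g2), 2 * (y2 - h2)], axis=-1) / denom
    grad = -(diou - dpen)
    return grad.reshape(np.asarray(p, dtype=np.float64).shape) if not isinstance(p, Box) else grad[0]


# ---------------------------------------------------------------------------
# differentiable (tensor) forms used by the training loop
# ---------------------------------------------------------------------------

def iou_t(p: T.Tensor, g: np.ndarray, kind: str = "mpdiou",
          ext: ImageExtent | None = None, eps: float = 1e-9) -> T.Tensor:
    """Differentiable overlap of predicted boxes (Tensor (N,4)) vs targets.

    ``kind`` selects plain IoU, CIoU or MPDIoU; returns a Tensor (N,).
    """
    g = np.asarray(g, dtype=np.float32)
    x1, y1, x2, y2 = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    ix = T.minimum(x2, g[:, 2]) - T.maximum(x1, g[:, 0])
    iy = T.minimum(y2, g[:, 3]) - T.maximum(y1, g[:, 1])
    inter = T.clip(ix, 0.0, np.inf) * T.clip(iy, 0.0, np.inf)
    area_p = (x2 - x1) * (y2 - y1)
    area_g = (g[:, 2] - g[:, 0]) * (g[:, 3] - g[:, 1])
    union = area_p + area_g - inter + eps
    base = inter / union
    if kind == "iou":
        return base
    if kind == "mpdiou":
        if ext is None:
            raise ValueError("mpdiou needs an ImageExtent")
        denom = ext.w ** 2 + ext.h ** 2
        d1 = (x1 - g[:, 0]) * (x1 - g[:, 0]) + (y1 - g[:, 1]) * (y1 - g[:, 1])
        d2 = (x2 - g[:, 2]) * (x2 - g[:, 2]) + (y2 - g[:, 3]) * (y2 - g[:, 3])
        return base - d1 * (1.0 / denom) - d2 * (1.0 / denom)
    if kind == "ciou":
        cxp, cyp = (x1 + x2) * 0.5, (y1 + y2) * 0.5
        cxg, cyg = (g[:, 0] + g[:, 2]) * 0.5, (g[:, 1] + g[:, 3]) * 0.5
        rho2 = (cxp - cxg) * (cxp - cxg) + (cyp - cyg) * (cyp - cyg)
        ex = T.maximum(x2, g[:, 2]) - T.minimum(x1, g[:, 0])
        ey = T.maximum(y2, g[:, 3]) - T.minimum(y1, g[:, 1])
        c2 = ex * ex + ey * ey + eps
        # aspect term with the standard detached weighting coefficient
        wp, hp = x2 - x1, y2 - y1
        wg, hg = g[:, 2] - g[:, 0], g[:, 3] - g[:, 1]
        atan_p = np.arctan(wp.data / np.maximum(hp.data, eps))
        m_val = (4.0 / np.pi ** 2) * (np.arctan(wg / hg) - atan_p) ** 2
        alpha = np.where(m_val > 0, m_val / (1.0 - base.data + m_val), 0.0)
        return base - rho2 / c2 - T.Tensor(alpha * m_val)
    raise ValueError(f"unknown overlap kind {kind!r}")
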