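"""Numerical correctness of the autodiff engine (finite-difference checks)."""

import numpy as np
import pytest

from pigstressnet.nn import tensor as T
from pigstressnet.nn.modules import BatchNorm2d, Conv


def numeric_grad(f, x, idx, eps=1e-3):
    xp, xm = x.copy(), x.copy()
    xp[idx] += eps
    xm[idx] -= eps
    return (f(xp) - f(xm)) / (2 * eps)


def check_grads(f, x, rng, n_checks=6, tol=2e-2):
    xt = T.Tensor(x, requires_grad=True)
    out = f(xt)
    go = rng.standard_normal(out.shape).astype(np.float32)
    out.backward(go)
    for _ in range(n_checks):
        idx = tuple(int(rng.integers(s)) for s in x.shape)
        fd = numeric_grad(lambda xx: float((f(T.Tensor(xx)).data * go).sum()), x, idx)
        assert xt.grad[idx] == pytest.approx(fd, abs=tol, rel=tol), idx


@pytest.mark.parametrize("op", [
    T.sigmoid, T.silu, T.relu6, T.relu, T.gelu,
    lambda x: T.softmax(x, axis=1),
    lambda x: x * x + 2.0 * x,
    lambda x: T.upsample_nearest2d(x, 2),
    lambda x: T.concat([x, x * 3.0], axis=1),
    lambda x: x.mean(axis=(2, 3)),
])
def test_pointwise_and_shape_ops(op, rng):
    x = rng.standard_normal((2, 3, 4, 4)).astype(np.float32)
    check_grads(op, x, rng)


def test_matmul_gradients(rng):
    a = rng.standard_normal((2, 3, 5)).astype(np.float32)
    b = rng.standard_normal((5, 4)).astype(np.float32)
    at = T.Tensor(a, requires_grad=True)
    bt = T.Tensor(b, requires_grad=True)
    out = T.matmul(at, bt)
    out.backward(np.ones(out.shape, np.float32))
    np.testing.assert_allclose(at.grad, np.ones((2, 3, 4)) @ b.T, atol=1e-5)
    np.testing.assert_allclose(bt.grad,
                               sum(a[i].T @ np.ones((3, 4)) for i in range(2)),
                               atol=1e-4)


@pytest.mark.parametrize("k,s,p,g", [(3, 1, 1, 1), (3, 2, 1, 1), (1, 1, 0, 1),
                                     (3, 1, 1, "dw"), ((1, 5), 1, (0, 2), "dw")])
def test_conv_gradients(k, s, p, g, rng):
    c = 6
    groups = c if g == "dw" else 1
    kh, kw = (k, k) if isinstance(k, int) else k
    x = rng.standard_normal((2, c, 8, 8)).astype(np.float32)
    w = rng.standard_normal((c if groups == c else 4, c // groups, kh, kw)).astype(np.float32)
    xt = T.Tensor(x, requires_grad=True)
    wt = T.Tensor(w, requires_grad=True)
    out = T.conv2d(xt, wt, None, s, p, groups)
    go = rng.standard_normal(out.shape).astype(np.float32)
    out.backward(go)

    def forward(xx, ww):
        return float((T.conv2d(T.Tensor(xx), T.Tensor(ww), None, s, p, groups).data * go).sum())

    for _ in range(4):
        idx = tuple(int(rng.integers(d)) for d in x.shape)
        fd = (forward(_bump(x, idx, 1e-3), w) - forward(_bump(x, idx, -1e-3), w)) / 2e-3
        assert xt.grad[idx] == pytest.approx(fd, abs=2e-2, rel=2e-2)
        widx = tuple(int(rng.integers(d)) for d in w.shape)
        fd = (forward(x, _bump(w, widx, 1e-3)) - forward(x, _bump(w, widx, -1e-3))) / 2e-3
        assert wt.grad[widx] == pytest.approx(fd, abs=2e-2, rel=2e-2)


def _bump(a, idx, eps):
    b = a.copy()
    b[idx] += eps
    return b


def test_batchnorm_training_gradients(rng):
    bn = BatchNorm2d(3)
    x = rng.standard_normal((4, 3, 5, 5)).astype(np.float32)

    def f(xt):
        bn.running_mean[:] = 0.0   # keep the buffer update from drifting
        bn.running_var[:] = 1.0
        return bn(xt)

    check_grads(f, x, rng)


def test_batchnorm_running_stats_track_batch(rng):
    bn = BatchNorm2d(2, momentum=1.0)
    x = rng.normal(3.0, 2.0, size=(8, 2, 6, 6)).astype(np.float32)
    bn(T.Tensor(x))
    np.testing.assert_allclose(bn.running_mean, x.mean(axis=(0, 2, 3)), atol=1e-4)
    bn.eval()
    out = bn(T.Tensor(x))
    # eval mode uses the captured statistics
    np.testing.assert_allclose(out.data.mean(axis=(0, 2, 3)), 0.0, atol=1e-3)


def test_conv_block_fused_count_convention():
    conv = Conv(8, 16, 3)
    # deployed: weights + one bias per output channel (BN folded)
    assert conv.deployed_param_count() == 9 * 8 * 16 + 16
    # raw trainable scalars keep the BN affine pair
    assert sum(p.data.size for p in conv.parameters()) == 9 * 8 * 16 + 32


def test_no_grad_suppresses_graph(rng):
    x = T.Tensor(rng.standard_normal((2, 2)).astype(np.float32), requires_grad=True)
    with T.no_grad():
        y = x * 3.0
    assert not y.requires_grad
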