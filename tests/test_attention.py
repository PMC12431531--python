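"""NAM weight normalisation, gating, regulariser; RCM structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pigstressnet.attention import (BatchNormState, NamChannelState,
                                    NamSpatialState, RCM, RcmState,
                                    batch_norm, nam_channel_forward,
                                    nam_channel_weights, nam_regularizer,
                                    nam_spatial_forward, rcm_forward)
from pigstressnet.nn import tensor as T


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestBatchNorm:
    def test_standardisation_identity(self, rng):
        x = rng.normal(3.0, 2.0, size=(6, 4, 5, 5))
        st_ = BatchNormState(x.mean(axis=(0, 2, 3)), x.var(axis=(0, 2, 3)),
                             np.ones(4), np.zeros(4), epsilon=1e-12)
        out = batch_norm(x, st_)
        np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 0.0, atol=1e-9)

    def test_zero_gamma_gives_constant_beta(self, rng):
        x = rng.normal(size=(2, 3, 4, 4))
        st_ = BatchNormState(np.zeros(3), np.ones(3), np.zeros(3),
                             np.full(3, 1.5))
        assert np.allclose(batch_norm(x, st_), 1.5)

    def test_hand_value(self):
        # x=[1,3], mu=2, var=1, eps->0, gamma=2, beta=1 -> [-1, 3]
        x = np.array([1.0, 3.0]).reshape(1, 1, 1, 2)
        st_ = BatchNormState([2.0], [1.0], [2.0], [1.0], epsilon=1e-15)
        np.testing.assert_allclose(batch_norm(x, st_).ravel(), [-1.0, 3.0],
                                   atol=1e-6)

    def test_channel_mismatch_raises(self, rng):
        st_ = BatchNormState(np.zeros(3), np.ones(3), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError, match="channel mismatch"):
            batch_norm(rng.normal(size=(1, 4, 2, 2)), st_)


class TestChannelWeights:
    def test_constant_scales_give_uniform(self):
        np.testing.assert_allclose(nam_channel_weights(np.full(8, 3.7)),
                                   np.full(8, 1 / 8))

    def test_hand_value(self):
        np.testing.assert_allclose(nam_channel_weights([2.0, 1.0, 1.0]),
                                   [0.5, 0.25, 0.25])

    def test_negative_scales_use_magnitude(self):
        np.testing.assert_allclose(nam_channel_weights([-2.0, 1.0, 1.0]),
                                   [0.5, 0.25, 0.25])

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=32))
    def test_weights_sum_to_one(self, gammas):
        g = np.array(gammas)
        if np.abs(g).sum() == 0:
            return
        assert nam_channel_weights(g).sum() == pytest.approx(1.0)

    def test_all_zero_policy(self):
        with pytest.raises(ValueError):
            nam_channel_weights(np.zeros(4))
        np.testing.assert_allclose(
            nam_channel_weights(np.zeros(4), zero_policy="uniform"), 0.25)


class TestRegularizer:
    def test_zero_balance(self):
        assert nam_regularizer([1, 2, 3], [4], p=0.0) == 0.0

    def test_hand_value(self):
        assert nam_regularizer([1.0, -2.0], [3.0], p=0.01) == pytest.approx(0.06)

    def test_monotone_in_gamma_magnitude(self, rng):
        g = rng.normal(size=8)
        base = nam_regularizer(g, [], p=1e-3)
        g2 = g.copy()
        g2[3] *= 2.0
        assert nam_regularizer(g2, [], p=1e-3) >= base


class TestGating:
    def test_channel_forward_hand_composed(self):
        f1 = np.arange(8, dtype=float).reshape(1, 2, 2, 2)
        bn = BatchNormState(mu_B=[1.0, 5.0], sigma2_B=[1.0, 1.0],
                            gamma=[2.0, 1.0], beta=[0.0, 0.5], epsilon=1e-15)
        state = NamChannelState(bn)
        out = nam_channel_forward(f1, state)
        w = np.array([2 / 3, 1 / 3])
        bn_ref = batch_norm(f1, bn)
        ref = f1 * _sigmoid(w.reshape(1, 2, 1, 1) * bn_ref)
        np.testing.assert_allclose(out, ref, atol=1e-12)
        assert out.shape == f1.shape

    def test_gate_strictly_in_unit_interval(self, rng):
        f1 = rng.normal(size=(2, 6, 4, 4))
        bn = BatchNormState(f1.mean(axis=(0, 2, 3)), f1.var(axis=(0, 2, 3)),
                            rng.normal(size=6), np.zeros(6))
        out = nam_channel_forward(f1, NamChannelState(bn))
        gate = np.where(np.abs(f1) > 1e-12, out / np.where(f1 == 0, 1, f1), 0.5)
        assert np.all(gate[np.abs(f1) > 1e-12] > 0)
        assert np.all(gate[np.abs(f1) > 1e-12] < 1)

    def test_nan_input_rejected(self):
        bn = BatchNormState([0.0], [1.0], [1.0], [0.0])
        bad = np.full((1, 1, 2, 2), np.nan)
        with pytest.raises(ValueError):
            nam_channel_forward(bad, NamChannelState(bn))

    def test_spatial_forward_hand_case(self):
        f2 = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        bn = BatchNormState(mu_B=np.zeros(4), sigma2_B=np.ones(4),
                            gamma=[1.0, 2.0, 3.0, 4.0], beta=np.zeros(4),
                            epsilon=1e-15)
        state = NamSpatialState(bn)
        out = nam_spatial_forward(f2, state)
        wl = np.array([1, 2, 3, 4]) / 10.0
        lam = np.array([1.0, 2.0, 3.0, 4.0])
        ref = f2.ravel() * _sigmoid(wl * (lam * f2.ravel()))
        np.testing.assert_allclose(out.ravel(), ref, atol=1e-12)
        assert state.weight_W_lambda.sum() == pytest.approx(1.0)


class TestRCM:
    def test_shape_preserved(self, rng):
        x = rng.normal(size=(1, 8, 16, 16)).astype(np.float32)
        out = rcm_forward(x, RcmState(channels=8))
        assert out.shape == x.shape

    def test_constant_input_has_constant_rectangle(self, rng):
        # axial pooling of a constant map is constant, so the rectangular
        # attention region before calibration is spatially flat
        x = np.full((1, 4, 6, 6), 2.5)
        x_h = x.mean(axis=3, keepdims=True)
        x_w = x.mean(axis=2, keepdims=True)
        rect = x_h + x_w
        assert np.ptp(rect) == 0.0

    def test_identity_configuration_passthrough(self, rng):
        m = RCM(8)
        # zero the MLP so the residual branch carries nothing
        m.fc2.weight.data[:] = 0.0
        m.fc2.bias.data[:] = 0.0
        m.eval()
        x = rng.normal(size=(1, 8, 12, 12)).astype(np.float32)
        out = m(T.Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    def test_gradient_reaches_input_everywhere(self, rng):
        m = RCM(4, strip_kernel=3)
        m.train()
        x = T.Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32),
                     requires_grad=True)
        out = m(x)
        (out.sum()).backward()
        assert x.grad is not None
        # no dead path: every input location receives gradient
        assert np.all(np.abs(x.grad) > 0)

    def test_invalid_strip_kernel(self):
        with pytest.raises(ValueError):
            RcmState(channels=8, strip_kernel=4)

    def test_calibrated_parameter_budget(self):
        # the configuration recorded in config: 64 channels, k=11, mlp x2
        m = RCM(64)
        assert m.deployed_param_count() == 19_072
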