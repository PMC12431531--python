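"""MBConv block behaviour and the closed-form convolution cost identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pigstressnet.mbconv import (ConvDims, MBConv, MBConvSpec, flops_conv,
                                 flops_dwconv, flops_ratio, mbconv_forward)

dims_st = st.builds(
    ConvDims,
    Kh=st.integers(1, 7), Kw=st.integers(1, 7),
    Cin=st.integers(1, 64), Cout=st.integers(1, 64),
    Hout=st.integers(1, 32), Wout=st.integers(1, 32),
)


class TestFlopsArithmetic:
    def test_dense_hand_value(self):
        d = ConvDims(3, 3, 16, 32, 8, 8)
        assert flops_conv(d) == 294_912

    def test_unit_dims(self):
        assert flops_conv(ConvDims(1, 1, 1, 1, 1, 1)) == 1

    def test_linear_in_spatial(self):
        d1 = ConvDims(3, 3, 4, 8, 8, 8)
        d2 = ConvDims(3, 3, 4, 8, 16, 8)
        assert flops_conv(d2) == 2 * flops_conv(d1)

    def test_separable_hand_value(self):
        d = ConvDims(3, 3, 16, 32, 8, 8)
        assert flops_dwconv(d) == 9_216 + 32_768

    def test_separable_degenerate(self):
        d = ConvDims(1, 1, 16, 1, 4, 4)
        assert flops_dwconv(d) == 2 * 16 * 16

    def test_ratio_hand_values(self):
        d = ConvDims(3, 3, 16, 32, 8, 8)
        assert float(flops_ratio(d)) == pytest.approx(1 / 32 + 1 / 9)
        assert float(flops_ratio(ConvDims(1, 1, 3, 1, 2, 2))) == 2.0
        assert float(flops_ratio(ConvDims(3, 3, 16, 64, 8, 8))) == pytest.approx(
            0.126736, abs=1e-6)

    def test_large_width_limit_approaches_one_ninth(self):
        # ~8-9x reduction for 3x3 kernels at large output width
        d = ConvDims(3, 3, 64, 4096, 8, 8)
        assert float(flops_ratio(d)) == pytest.approx(1 / 9, abs=1e-3)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(dims_st)
    def test_separable_equals_dense_times_ratio(self, d):
        assert flops_dwconv(d) == flops_conv(d) * flops_ratio(d)

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            ConvDims(0, 3, 1, 1, 1, 1)


class TestMBConvBlock:
    def test_skip_when_shape_preserved(self, rng):
        spec = MBConvSpec(16, 16, expansion_t=4)
        m = MBConv(spec)
        # zero the projection: with a live skip the block is the identity
        m.project.weight.data[:] = 0.0
        x = rng.normal(size=(1, 16, 6, 6)).astype(np.float32)
        out = mbconv_forward(x, spec, m)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_no_skip_on_channel_change(self, rng):
        spec = MBConvSpec(16, 32, expansion_t=4)
        x = rng.normal(size=(2, 16, 6, 6)).astype(np.float32)
        out = mbconv_forward(x, spec)
        assert out.shape == (2, 32, 6, 6)
        assert spec.has_skip is False

    def test_stride_halves_resolution(self, rng):
        spec = MBConvSpec(8, 16, stride=2)
        out = mbconv_forward(rng.normal(size=(1, 8, 8, 8)).astype(np.float32), spec)
        assert out.shape == (1, 16, 4, 4)

    def test_deterministic(self, rng):
        spec = MBConvSpec(8, 8)
        m = MBConv(spec)
        x = rng.normal(size=(1, 8, 5, 5)).astype(np.float32)
        np.testing.assert_array_equal(mbconv_forward(x, spec, m),
                                      mbconv_forward(x, spec, m))

    def test_param_count_matches_layerwise_enumeration(self):
        # independent oracle: sum each layer's parameter formula
        spec = MBConvSpec(16, 24, expansion_t=4, kernel=3, se_ratio=0.25)
        m = MBConv(spec)
        h = spec.hidden        # 64
        s = spec.squeeze       # 4
        expect = (
            (16 * h + 2 * h)            # expand conv + bn
            + (9 * h + 2 * h)           # depthwise + bn
            + (h * s + s + s * h + h)   # SE reduce/expand with biases
            + (h * 24 + 2 * 24)         # projection + bn
        )
        got = sum(p.data.size for p in m.parameters())
        assert got == expect

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            MBConvSpec(8, 8, kernel=4)
        with pytest.raises(ValueError):
            MBConvSpec(8, 8, se_ratio=0.0)
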