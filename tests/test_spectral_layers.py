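"""LSBDU and depthwise separable convolution against brute-force oracles."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from spectracell._nn import LSBDULayer
from spectracell.filterbank import bior22_taps, make_kernels
from spectracell.spectral_layers import (DSCParams, LSBDUParams, dsc_forward,
                                         init_lsbdu, lsbdu_attention,
                                         lsbdu_forward)


def oracle_lsbdu(x: np.ndarray, p: LSBDUParams) -> np.ndarray:
    """Independent route: full-resolution correlation, then slice [::2]."""
    h, w, c = x.shape
    out = np.zeros((-(-h // 2), -(-w // 2), c))
    for ch in range(c):
        low = correlate2d(x[:, :, ch], p.phi[ch], mode="same", boundary="symm")
        high = correlate2d(x[:, :, ch], p.psi[ch], mode="same", boundary="symm")
        alpha = 1.0 / (1.0 + np.exp(-p.a[ch]))
        beta = 1.0 / (1.0 + np.exp(-p.b[ch]))
        out[:, :, ch] = (alpha * low + beta * high)[::2, ::2]
    return out


def oracle_dsc(x: np.ndarray, p: DSCParams) -> np.ndarray:
    """Per-channel correlation then per-pixel matrix multiply."""
    h, w, m = x.shape
    mid = np.stack([correlate2d(x[:, :, ch], p.depthwise[ch], mode="same",
                                boundary="symm") for ch in range(m)], axis=-1)
    out = mid @ p.pointwise
    if p.bias is not None:
        out = out + p.bias
    return out


class TestLSBDUForward:
    @pytest.mark.parametrize("h", range(2, 18))
    @pytest.mark.parametrize("w", [2, 5, 11, 17])
    @pytest.mark.parametrize("c", [1, 3, 8])
    def test_shape_halving(self, h, w, c, rng):
        x = rng.random((h, w, c))
        out = lsbdu_forward(x, init_lsbdu(c))
        assert out.shape == (-(-h // 2), -(-w // 2), c)

    def test_example_shape_8x8x4(self, rng):
        assert lsbdu_forward(rng.random((8, 8, 4)), init_lsbdu(4)).shape == (4, 4, 4)

    @pytest.mark.parametrize("value", [1.0, 2.0, -0.5])
    def test_constant_input_gives_half_value(self, value):
        # sigma(0) = 0.5, phi has DC gain 1, psi kills constants
        x = np.full((8, 8, 3), value)
        out = lsbdu_forward(x, init_lsbdu(3))
        np.testing.assert_allclose(out, 0.5 * value, atol=1e-10)

    @pytest.mark.parametrize("h,w", [(6, 6), (7, 9), (12, 12), (11, 6)])
    def test_matches_bruteforce_oracle_random_params(self, h, w, rng):
        c = 3
        p = LSBDUParams(phi=rng.normal(size=(c, 3, 3)),
                        psi=rng.normal(size=(c, 3, 3)),
                        a=rng.normal(size=c), b=rng.normal(size=c))
        # oracle ignores the TapPair symmetry; any kernels are valid here
        x = rng.random((h, w, c))
        np.testing.assert_allclose(lsbdu_forward(x, p), oracle_lsbdu(x, p), atol=1e-5)

    def test_linearity_in_input(self, rng):
        p = init_lsbdu(2)
        p.a, p.b = rng.normal(size=2), rng.normal(size=2)
        x = rng.random((10, 10, 2))
        np.testing.assert_allclose(lsbdu_forward(3.5 * x, p),
                                   3.5 * lsbdu_forward(x, p), atol=1e-10)

    def test_batched_input(self, rng):
        x = rng.random((4, 8, 8, 2))
        p = init_lsbdu(2)
        batched = lsbdu_forward(x, p)
        assert batched.shape == (4, 4, 4, 2)
        np.testing.assert_allclose(batched[1], lsbdu_forward(x[1], p), atol=1e-12)

    def test_channel_mismatch_and_tiny_input_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            lsbdu_forward(rng.random((8, 8, 3)), init_lsbdu(4))
        with pytest.raises(ValueError, match="spatial"):
            lsbdu_forward(rng.random((1, 8, 3)), init_lsbdu(3))


class TestLSBDUAttention:
    def test_constant_input_gives_zero_map(self):
        att = lsbdu_attention(np.full((10, 10, 3), 0.7), init_lsbdu(3))
        np.testing.assert_array_equal(att, 0.0)

    def test_range_and_shape(self, rng):
        x = rng.random((9, 12, 4))
        att = lsbdu_attention(x, init_lsbdu(4))
        assert att.shape == lsbdu_forward(x, init_lsbdu(4)).shape[:2]
        assert att.min() >= 0.0 and att.max() <= 1.0


class TestDSC:
    def test_identity_configuration(self, rng):
        m = 3
        delta = np.zeros((m, 3, 3))
        delta[:, 1, 1] = 1.0
        p = DSCParams(depthwise=delta, pointwise=np.eye(m), bias=np.zeros(m))
        x = rng.random((7, 7, m))
        np.testing.assert_allclose(dsc_forward(x, p), x, atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        p = DSCParams(depthwise=rng.normal(size=(4, 3, 3)),
                      pointwise=rng.normal(size=(4, 6)),
                      bias=rng.normal(size=6))
        x = rng.random((10, 8, 4))
        np.testing.assert_allclose(dsc_forward(x, p), oracle_dsc(x, p), atol=1e-5)

    def test_output_channel_shape(self, rng):
        p = DSCParams(depthwise=rng.normal(size=(3, 3, 3)),
                      pointwise=rng.normal(size=(3, 8)))
        assert dsc_forward(rng.random((16, 16, 3)), p).shape == (16, 16, 8)

    def test_channel_mismatch_rejected(self, rng):
        p = DSCParams(depthwise=rng.normal(size=(3, 3, 3)),
                      pointwise=rng.normal(size=(3, 8)))
        with pytest.raises(ValueError, match="channels"):
            dsc_forward(rng.random((8, 8, 5)), p)


class TestInit:
    def test_shared_bior_initialization(self):
        p = init_lsbdu(4)
        kern = make_kernels(bior22_taps())
        for ch in range(4):
            np.testing.assert_allclose(p.phi[ch], kern.phi, atol=1e-12)
            assert p.phi[ch].sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(p.alpha, 0.5, atol=1e-15)
        np.testing.assert_allclose(p.beta, 0.5, atol=1e-15)

    def test_nonpositive_channel_count_rejected(self):
        with pytest.raises(ValueError):
            init_lsbdu(0)


class TestGradients:
    def test_finite_difference_check_on_6x6x2(self, rng):
        """All LSBDU parameter gradients agree with central differences."""
        kern = make_kernels(bior22_taps())
        layer = LSBDULayer(2, kern.phi, kern.psi)
        for key in layer.params:
            layer.params[key] = layer.params[key].astype(np.float64)
        layer.params["a"] = rng.normal(0, 0.3, 2)
        layer.params["b"] = rng.normal(0, 0.3, 2)
        x = rng.random((1, 2, 6, 6))

        def loss(xx):
            return float((layer.forward(xx, True) ** 2).sum())

        out = layer.forward(x, True)
        gx = layer.backward(2 * out, need_input_grad=True)
        eps = 1e-6
        num = np.zeros_like(x)
        for idx in np.ndindex(x.shape):
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num[idx] = (loss(xp) - loss(xm)) / (2 * eps)
        assert np.abs(num - gx).max() < 1e-3
        for key in ("phi", "psi", "a", "b"):
            ana = layer.grads[key]
            num = np.zeros_like(layer.params[key])
            for idx in np.ndindex(layer.params[key].shape):
                orig = layer.params[key][idx]
                layer.params[key][idx] = orig + eps
                lp = loss(x)
                layer.params[key][idx] = orig - eps
                lm = loss(x)
                layer.params[key][idx] = orig
                num[idx] = (lp - lm) / (2 * eps)
            assert np.abs(num - ana).max() < 1e-3, key

    def test_fusion_weights_stay_in_unit_interval_after_training(self, rng):
        """50 gradient steps keep every sigmoid gate strictly inside (0,1)."""
        kern = make_kernels(bior22_taps())
        layer = LSBDULayer(3, kern.phi, kern.psi)
        x = rng.random((2, 3, 8, 8)).astype(np.float32)
        target = rng.random((2, 3, 4, 4)).astype(np.float32)
        for _ in range(50):
            out = layer.forward(x, True)
            layer.backward(2 * (out - target), need_input_grad=False)
            for key in ("a", "b"):
                layer.params[key] = layer.params[key] - 0.1 * layer.grads[key]
        for key in ("a", "b"):
            gates = 1.0 / (1.0 + np.exp(-layer.params[key]))
            assert np.all((gates > 0) & (gates < 1))
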