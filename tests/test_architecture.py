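"""Model assembly, softmax head, cost accounting, checkpoints."""

import itertools
import math

import numpy as np
import pytest

from spectracell._nn import Conv3x3, Linear, LSBDULayer, Model
from spectracell.architecture import (ArchitectureSpec, build_model, cost_dsc,
                                      cost_standard, count_parameters,
                                      default_spec, load_checkpoint,
                                      model_cost_report, predict_proba,
                                      save_checkpoint, small_spec, softmax)


class TestSoftmax:
    def test_uniform_logits_give_uniform_distribution(self):
        np.testing.assert_allclose(softmax(np.zeros(8)), 0.125, atol=1e-15)

    def test_hand_computed_two_class_case(self):
        np.testing.assert_allclose(softmax(np.array([math.log(2.0), 0.0])),
                                   [2 / 3, 1 / 3], atol=1e-12)

    @pytest.mark.parametrize("shift", [-100.0, 3.3, 1e4])
    def test_shift_invariance(self, shift, rng):
        z = rng.normal(size=6)
        np.testing.assert_allclose(softmax(z + shift), softmax(z), atol=1e-12)

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([1.0, np.inf]))

    def test_sums_to_one_on_many_random_vectors(self, rng):
        z = rng.normal(scale=50, size=(1000, 8))
        s = softmax(z)
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-6)
        assert (s >= 0).all()


def oracle_mac_count(dk, m, n, df, separable):
    """Count multiply–accumulates one by one over a same-padded stride-1 conv."""
    macs = 0
    for _out_y, _out_x in itertools.product(range(df), range(df)):
        if separable:
            for _c, _ky, _kx in itertools.product(range(m), range(dk), range(dk)):
                macs += 1  # depthwise multiply
            for _c, _o in itertools.product(range(m), range(n)):
                macs += 1  # pointwise multiply
        else:
            for _o, _c, _ky, _kx in itertools.product(range(n), range(m),
                                                      range(dk), range(dk)):
                macs += 1
    return macs


class TestCosts:
    def test_standard_cost_examples(self):
        assert cost_standard(3, 32, 64, 56) == 57_802_752
        assert cost_standard(1, 1, 1, 1) == 1
        assert cost_standard(3, 1, 1, 8) == 576

    def test_dsc_cost_example(self):
        assert cost_dsc(3, 32, 64, 56) == 7_325_696
        m, n, df = 5, 7, 4
        assert cost_dsc(1, m, n, df) == m * df * df * (1 + n)

    def test_costs_match_bruteforce_mac_enumeration(self, rng):
        for _ in range(20):
            dk = int(rng.choice([1, 3]))
            m, n = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            df = int(rng.integers(1, 5))
            assert cost_standard(dk, m, n, df) == oracle_mac_count(dk, m, n, df, False)
            assert cost_dsc(dk, m, n, df) == oracle_mac_count(dk, m, n, df, True)

    def test_ratio_identity(self, rng):
        for _ in range(20):
            dk = int(rng.integers(1, 8))
            m = int(rng.integers(1, 512))
            n = int(rng.integers(1, 512))
            df = int(rng.integers(1, 128))
            ratio = cost_dsc(dk, m, n, df) / cost_standard(dk, m, n, df)
            assert ratio == pytest.approx(1 / n + 1 / dk ** 2, abs=1e-12)

    def test_dsc_cheaper_exactly_when_ratio_below_one(self):
        # 1/N + 1/DK² < 1 requires both N > 1 and DK > 1
        for dk, n in [(2, 8), (3, 2), (3, 64), (5, 8)]:
            assert cost_dsc(dk, 16, n, 10) < cost_standard(dk, 16, n, 10)
        for dk, n in [(1, 2), (3, 1), (1, 1)]:
            assert cost_dsc(dk, 16, n, 10) >= cost_standard(dk, 16, n, 10)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            cost_standard(0, 1, 1, 1)
        with pytest.raises(ValueError):
            cost_dsc(3, -2, 1, 1)

    def test_model_cost_report_totals(self):
        rep = model_cost_report(small_spec())
        assert rep.standard_macs > rep.dsc_macs > 0
        assert rep.ratio == pytest.approx(rep.dsc_macs / rep.standard_macs)


class TestBuildModel:
    def test_forward_gives_probability_vector(self, rng):
        model = build_model(small_spec(), seed=1)
        probs = predict_proba(model, rng.random((64, 64, 3)).astype(np.float32))
        assert probs.shape == (8,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert (probs >= 0).all()

    def test_default_spec_reaches_7x7_before_gap(self, rng):
        model = build_model(default_spec(), seed=0)
        x = rng.random((1, 3, 224, 224)).astype(np.float32)
        model.forward(x, train=False)
        last_down = [n for n in model.layer_names if n.endswith(".down")][-1]
        assert model.activation(last_down).shape[2:] == (7, 7)

    def test_maxpool_variant_has_fewer_parameters(self):
        lsbdu = build_model(small_spec(downsampler="lsbdu"), seed=0)
        pool = build_model(small_spec(downsampler="maxpool"), seed=0)
        channels = [32, 64, 96]  # one LSBDU per stage at these widths
        expected_gap = sum(20 * c for c in channels)
        assert count_parameters(lsbdu) - count_parameters(pool) == expected_gap

    def test_spatial_collapse_rejected(self):
        with pytest.raises(ValueError, match="collapse"):
            ArchitectureSpec(input_size=(8, 8, 3), stem_channels=4,
                             stages=[(1, 8)] * 5, num_classes=8)

    def test_forward_determinism_bit_identical(self, rng):
        model = build_model(small_spec(), seed=3)
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        out1 = model.forward(x, train=False)
        out2 = model.forward(x, train=False)
        assert out1.tobytes() == out2.tobytes()


class TestCountParameters:
    def test_single_conv_with_bias(self, rng):
        conv = Conv3x3(3, 8, rng)
        assert Model([("c", conv)]).count_parameters() == 3 * 3 * 3 * 8 + 8

    def test_fully_connected_with_bias(self, rng):
        fc = Linear(512, 8, rng)
        assert Model([("fc", fc)]).count_parameters() == 512 * 8 + 8

    def test_lsbdu_adds_20_per_channel(self):
        from spectracell.filterbank import bior22_taps, make_kernels
        k = make_kernels(bior22_taps())
        for c in (1, 5, 32):
            layer = LSBDULayer(c, k.phi, k.psi)
            assert Model([("d", layer)]).count_parameters() == 20 * c

    def test_matches_enumeration_over_random_specs(self, rng):
        for _ in range(5):
            stages = [(int(rng.integers(1, 3)), int(rng.integers(4, 17)))
                      for _ in range(int(rng.integers(1, 4)))]
            spec = ArchitectureSpec(input_size=(32, 32, 3),
                                    stem_channels=int(rng.integers(4, 9)),
                                    stages=stages, num_classes=8)
            model = build_model(spec, seed=0)
            # oracle: walk every parameter array independently of the method
            total = sum(arr.size for name, arr in model.state_dict().items()
                        if ".buffer." not in name)
            assert count_parameters(model) == total


class TestCheckpoints:
    def test_roundtrip_preserves_outputs(self, tmp_path, rng):
        spec = small_spec()
        model = build_model(spec, seed=5)
        x = rng.random((64, 64, 3)).astype(np.float32)
        before = predict_proba(model, x)
        save_checkpoint(model, spec, str(tmp_path / "ckpt"),
                        extra={"mean": [0.5] * 3, "std": [0.2] * 3})
        restored, spec2, extra = load_checkpoint(str(tmp_path / "ckpt"))
        np.testing.assert_allclose(predict_proba(restored, x), before, atol=1e-7)
        assert spec2.stages == spec.stages
        assert extra["mean"] == [0.5] * 3
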