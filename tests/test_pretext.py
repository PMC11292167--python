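"""Masked-prediction and transformation-prediction supervision."""

import math

import numpy as np
import pytest

from e4mood.pretext import (
    DEFAULT_TRANSFORM_PARAMS,
    MaskSpec,
    TRANSFORM_KINDS,
    TransformAssignment,
    apply_mask,
    apply_transform,
    mp_loss,
    sample_mask,
    sample_segment_masks,
    sample_transforms,
    tp_loss,
)

from conftest import make_segment


class TestMaskSpec:
    def test_l1_derived_from_l0_and_ratio(self):
        spec = MaskSpec(r=0.15, l0_seconds=3.0)
        assert spec.l0_samples(32) == 96
        assert spec.l1_samples(32) == pytest.approx(96 * 0.85 / 0.15)  # 544

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            MaskSpec(r=0.0)
        with pytest.raises(ValueError):
            MaskSpec(l0_seconds=-1)


class TestMaskSampling:
    def test_masked_fraction_converges_to_ratio(self):
        rng = np.random.default_rng(0)
        spec = MaskSpec()
        masked = sum(sample_mask(200_000, spec, rng, fs=32).sum() for _ in range(5))
        assert masked / 1_000_000 == pytest.approx(spec.r, abs=0.005)

    def test_masked_run_mean_converges_to_l0(self):
        rng = np.random.default_rng(1)
        spec = MaskSpec()
        lengths = []
        while len(lengths) < 10_000:
            m = sample_mask(500_000, spec, rng, fs=32)
            d = np.diff(np.concatenate([[0], m.astype(np.int8), [0]]))
            lengths.extend((np.where(d == -1)[0] - np.where(d == 1)[0]).tolist())
        assert np.mean(lengths) / 32.0 == pytest.approx(3.0, rel=0.02)

    def test_masks_scale_with_channel_rate(self, tiny_segment):
        masks = sample_segment_masks(tiny_segment, MaskSpec(), np.random.default_rng(0))
        for name, values in tiny_segment.channels.items():
            assert len(masks[name]) == len(values)


class TestApplyMask:
    def test_all_unmasked_is_identity(self, tiny_segment):
        masks = {k: np.zeros(len(v), bool) for k, v in tiny_segment.channels.items()}
        out = apply_mask(tiny_segment, masks)
        for name in tiny_segment.channels:
            np.testing.assert_array_equal(out.channels[name], tiny_segment.channels[name])

    def test_all_masked_zeroes_everything(self, tiny_segment):
        masks = {k: np.ones(len(v), bool) for k, v in tiny_segment.channels.items()}
        out = apply_mask(tiny_segment, masks)
        for name in tiny_segment.channels:
            np.testing.assert_array_equal(out.channels[name], 0.0)

    def test_exactly_k_positions_altered(self):
        seg = make_segment(fill=1.0)
        masks = {k: np.zeros(len(v), bool) for k, v in seg.channels.items()}
        masks["bvp"][:5] = True
        out = apply_mask(seg, masks)
        altered = sum(int((out.channels[k] != seg.channels[k]).sum()) for k in seg.channels)
        assert altered == 5


class TestMpLoss:
    def test_perfect_reconstruction_is_zero(self):
        x = {"a": np.arange(10.0)}
        assert mp_loss(x, {"a": np.arange(10.0)}, {"a": np.ones(10, bool)}) == 0.0

    def test_unit_error_closed_form(self):
        x = {"a": np.ones(8)}
        m = {"a": np.zeros(8, bool)}
        m["a"][:4] = True
        assert mp_loss(x, {"a": np.zeros(8)}, m) == pytest.approx(1.0)

    def test_depends_only_on_masked_coordinates(self):
        rng = np.random.default_rng(2)
        x = {"a": rng.normal(size=50)}
        xh = {"a": rng.normal(size=50)}
        m = {"a": rng.random(50) < 0.3}
        base = mp_loss(x, xh, m)
        perturbed = {"a": xh["a"] + (~m["a"]) * rng.normal(size=50) * 100}
        assert mp_loss(x, perturbed, m) == pytest.approx(base)

    def test_empty_mask_is_undefined(self):
        with pytest.raises(ValueError):
            mp_loss({"a": np.ones(4)}, {"a": np.ones(4)}, {"a": np.zeros(4, bool)})


class TestTransforms:
    def test_uniform_sampling_over_kinds(self):
        rng = np.random.default_rng(3)
        counts = {k: 0 for k in TRANSFORM_KINDS}
        draws = 10_000
        for _ in range(draws):
            for kind in sample_transforms(6, rng).kinds:
                counts[kind] += 1
        for kind in TRANSFORM_KINDS:
            assert counts[kind] / (6 * draws) == pytest.approx(1 / 6, abs=0.01)

    def test_assignment_reproducible_and_complete(self):
        a = sample_transforms(6, np.random.default_rng(7))
        b = sample_transforms(6, np.random.default_rng(7))
        assert a.kinds == b.kinds and len(a.kinds) == 6

    def test_identity_is_bit_exact(self):
        x = np.random.default_rng(0).normal(size=100)
        np.testing.assert_array_equal(apply_transform(x, "identity"), x)

    def test_gaussian_noise_sd(self):
        rng = np.random.default_rng(4)
        x = np.zeros(200_000)
        out = apply_transform(x, "gaussian_noise", {"sigma": 0.1}, rng)
        assert np.std(out - x) == pytest.approx(0.1, rel=0.02)

    def test_permutation_preserves_multiset(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=101)  # deliberately not divisible by 4
        out = apply_transform(x, "permutation", None, rng)
        np.testing.assert_allclose(np.sort(out), np.sort(x))

    @pytest.mark.parametrize("kind", TRANSFORM_KINDS)
    def test_length_preserved_and_non_identity_alters(self, kind):
        rng = np.random.default_rng(6)
        x = rng.normal(size=256)
        out = apply_transform(x, kind, None, rng)
        assert len(out) == len(x)
        if kind != "identity":
            assert not np.array_equal(out, x)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            apply_transform(np.zeros(4), "mystery", None, np.random.default_rng(0))


class TestTpLoss:
    def test_uniform_prediction_is_ln6(self):
        logits = np.zeros((6, 6))
        labels = TransformAssignment(kinds=TRANSFORM_KINDS)
        assert tp_loss(logits, labels) == pytest.approx(math.log(6))

    def test_one_hot_correct_prediction_is_zero(self):
        labels = np.array([0, 3, 5, 1, 2, 4])
        logits = np.full((6, 6), -1e4)
        logits[np.arange(6), labels] = 1e4
        assert tp_loss(logits, labels) == pytest.approx(0.0, abs=1e-9)

    def test_half_uniform_half_correct_averages(self):
        labels = np.zeros(6, dtype=int)
        logits = np.zeros((6, 6))
        logits[3:, 0] = 1e4  # three channels confidently correct
        assert tp_loss(logits, labels) == pytest.approx(math.log(6) / 2, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tp_loss(np.zeros((6, 5)), np.zeros(6, dtype=int))
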