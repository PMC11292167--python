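"""Wear detection, sleep scoring, segmentation and standardization rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from e4mood.preprocess import (
    OFF_BODY, SLEEP, WAKE,
    compute_arm_angle,
    detect_off_body,
    detect_sleep_wake,
    enforce_min_wear_run,
    fit_normalization,
    segment_wake_spans,
    standardize,
)
from e4mood.session import ChannelSeries, SessionRecord

from conftest import make_segment


def _series(name, per_second, fs):
    return ChannelSeries(name, np.repeat(np.asarray(per_second, float), int(fs)), fs, 0.0)


class TestOffBody:
    def test_normal_values_are_on_body(self):
        off = detect_off_body(_series("eda", [0.2] * 20, 4), _series("temp", [33.0] * 20, 4))
        assert not off.any()

    def test_low_eda_sample_marks_its_second(self):
        eda = np.full(80, 0.2)
        eda[4 * 7] = 0.04  # one sample inside second 7
        off = detect_off_body(ChannelSeries("eda", eda, 4, 0.0),
                              _series("temp", [33.0] * 20, 4))
        assert off[7] and off.sum() == 1

    def test_temp_out_of_range_marks_seconds(self):
        temp = [33.0] * 10 + [42.0] * 10
        off = detect_off_body(_series("eda", [0.2] * 20, 4), _series("temp", temp, 4))
        assert not off[:10].any() and off[10:].all()

    def test_eda_above_sensor_range_is_off_body(self):
        off = detect_off_body(_series("eda", [150.0] * 10, 4), _series("temp", [33.0] * 10, 4))
        assert off.all()


class TestMinWearRun:
    def test_short_run_relabeled(self):
        off = np.ones(1000, bool)
        off[300:599] = False  # 299 s on-body
        assert enforce_min_wear_run(off).all()

    def test_exact_five_minutes_kept(self):
        off = np.ones(1000, bool)
        off[300:600] = False  # exactly 300 s
        out = enforce_min_wear_run(off)
        assert not out[300:600].any()

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        off = rng.random(2000) < 0.3
        once = enforce_min_wear_run(off)
        np.testing.assert_array_equal(once, enforce_min_wear_run(once))


class TestArmAngle:
    @pytest.mark.parametrize("xyz,expected", [
        ((0, 0, 1), 90.0),
        ((1, 0, 0), 0.0),
        ((0, 1, 1), 45.0),
    ])
    def test_constant_orientation_closed_form(self, xyz, expected):
        n = 32 * 10
        angles = compute_arm_angle(*[np.full(n, float(v)) for v in xyz], fs=32)
        np.testing.assert_allclose(angles, expected, atol=1e-9)

    def test_zero_norm_epoch_is_flat(self):
        z = np.zeros(32 * 5)
        assert compute_arm_angle(z, z, z, fs=32)[0] == 0.0


class TestSleepWake:
    def test_ten_minutes_still_is_sleep(self):
        angles = np.full(120, 30.0)  # 120 epochs = 600 s
        tl = detect_sleep_wake(angles, np.zeros(600, bool))
        assert (tl.statuses == SLEEP).all()

    def test_alternating_angles_are_wake(self):
        angles = np.where(np.arange(120) % 6 < 3, 10.0, 20.0)  # ±10° every 30 s
        tl = detect_sleep_wake(angles, np.zeros(600, bool))
        assert (tl.statuses == WAKE).all()

    def test_four_minute_still_run_is_wake(self):
        angles = np.concatenate([np.full(48, 30.0),  # 240 s still
                                 30.0 + 20.0 * np.arange(72)])  # then movement
        tl = detect_sleep_wake(angles, np.zeros(600, bool))
        assert (tl.statuses == WAKE).all()

    def test_off_body_seconds_keep_status(self):
        angles = np.full(120, 30.0)
        off = np.zeros(600, bool)
        off[:100] = True
        tl = detect_sleep_wake(angles, off)
        assert (tl.statuses[:100] == OFF_BODY).all()

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        angles = rng.uniform(0, 90, size=240)
        off = rng.random(1200) < 0.2
        tl = detect_sleep_wake(angles, off)
        assert set(np.unique(tl.statuses)) <= {OFF_BODY, SLEEP, WAKE}
        np.testing.assert_array_equal(tl.statuses == OFF_BODY, off)


def _wake_session(n_seconds):
    fs_map = {"acc_x": 32, "acc_y": 32, "acc_z": 32, "bvp": 64, "eda": 4, "temp": 4}
    rng = np.random.default_rng(0)
    channels = {
        name: ChannelSeries(name, rng.normal(size=int(fs * n_seconds)), fs, 0.0)
        for name, fs in fs_map.items()
    }
    return SessionRecord("r0", "s0", label="acute", channels=channels)


class TestSegmentation:
    @pytest.mark.parametrize("L,expected", [(1024, 5), (511, 0), (512, 1)])
    def test_window_counts(self, L, expected):
        from e4mood.preprocess import StatusTimeline
        session = _wake_session(L)
        tl = StatusTimeline(np.full(L, WAKE, np.int8))
        segs = segment_wake_spans(session, tl, omega=512, step=128)
        assert len(segs) == expected

    @given(L=st.integers(min_value=0, max_value=700), omega=st.integers(16, 128),
           step=st.integers(8, 64))
    def test_count_formula_property(self, L, omega, step):
        from e4mood.preprocess import StatusTimeline
        session = _wake_session(max(L, 1))
        tl = StatusTimeline(np.full(max(L, 1), WAKE, np.int8))
        tl.statuses[L:] = OFF_BODY
        segs = segment_wake_spans(session, tl, omega=omega, step=step)
        expected = 0 if L < omega else (L - omega) // step + 1
        assert len(segs) == expected
        for s in segs:
            assert all(len(v) == omega * session.channels[k].fs
                       for k, v in s.channels.items())

    def test_segments_never_straddle_non_wake(self):
        from e4mood.preprocess import StatusTimeline
        session = _wake_session(2000)
        statuses = np.full(2000, WAKE, np.int8)
        statuses[900:1000] = OFF_BODY
        tl = StatusTimeline(statuses)
        segs = segment_wake_spans(session, tl, omega=512, step=128)
        for s in segs:
            assert (statuses[s.start_offset:s.start_offset + 512] == WAKE).all()


class TestNormalization:
    def test_hand_computed_mean_sd(self):
        a = make_segment(fill=0.0)
        b = make_segment(fill=2.0)
        stats = fit_normalization([a, b])
        for name in a.channels:
            assert stats.mean[name] == pytest.approx(1.0)
            assert stats.sd[name] == pytest.approx(1.0)  # population SD of {0,2}

    def test_constant_channel_flagged_and_zeroed(self):
        seg = make_segment(fill=3.0)
        stats = fit_normalization([seg])
        assert set(stats.degenerate) == set(seg.channels)
        out = standardize(seg, stats)
        for v in out.channels.values():
            np.testing.assert_array_equal(v, 0.0)

    def test_self_standardization_is_zero_mean_unit_sd(self):
        rng = np.random.default_rng(7)
        segs = [make_segment(rng=rng) for _ in range(4)]
        stats = fit_normalization(segs)
        z = [standardize(s, stats) for s in segs]
        for name in segs[0].channels:
            pooled = np.concatenate([s.channels[name] for s in z])
            assert abs(pooled.mean()) < 1e-9
            assert pooled.std() == pytest.approx(1.0, abs=1e-9)

    def test_double_standardization_with_refit_is_identity_like(self):
        rng = np.random.default_rng(8)
        segs = [make_segment(rng=rng) for _ in range(3)]
        stats = fit_normalization(segs)
        z = [standardize(s, stats) for s in segs]
        stats2 = fit_normalization(z)
        z2 = [standardize(s, stats2) for s in z]
        for s1, s2 in zip(z, z2):
            for name in s1.channels:
                np.testing.assert_allclose(s1.channels[name], s2.channels[name], atol=1e-9)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            fit_normalization([])
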