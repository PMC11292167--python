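"""Splits, balancing, scheduler, vote metrics, correlations, comparisons."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from e4mood.preprocess import Segment
from e4mood.train import (
    SchedulerState,
    balance_classes,
    compare_models,
    evaluate,
    pearson_corr,
    scheduler_step,
    split_unlabeled,
    time_split_target,
)

from conftest import make_segment


def _seg(session, start, omega=64):
    s = make_segment(omega=8, subject=session, session=session, start=start)
    # overwrite with a nominal omega for interval arithmetic without big arrays
    s.channels = {"eda": np.zeros(int(omega * 4))}
    s.fs = {"eda": 4.0}
    return s


class TestUnlabeledSplit:
    def test_twenty_recordings_split_17_3(self):
        ids = [f"r{i}" for i in range(20)]
        split = split_unlabeled(ids, seed=0)
        counts = list(split.values())
        assert counts.count("train") == 17 and counts.count("val") == 3

    def test_partition_and_determinism(self):
        ids = [f"r{i}" for i in range(9)]
        a = split_unlabeled(ids, seed=4)
        b = split_unlabeled(ids, seed=4)
        assert a == b
        assert set(a) == set(ids)

    def test_too_few_recordings(self):
        with pytest.raises(ValueError):
            split_unlabeled(["only"])


class TestTimeSplit:
    def test_ratios_must_sum_to_one(self):
        with pytest.raises(ValueError):
            time_split_target([], ratios=(0.5, 0.2, 0.2))

    @given(duration=st.integers(300, 3000), omega=st.integers(32, 128),
           step=st.integers(16, 128))
    def test_brute_force_interval_containment(self, duration, omega, step):
        """Every retained segment lies wholly inside its split's window."""
        starts = list(range(0, duration - omega + 1, step))
        segments = [_seg("rec", s, omega) for s in starts]
        split = time_split_target(segments, durations={"rec": duration})
        b1, b2 = 0.70 * duration, 0.85 * duration
        for seg, assigned in zip(segments, split.segment_split):
            lo, hi = seg.start_offset, seg.start_offset + omega
            # brute-force reference decision
            if hi <= b1:
                expected = "train"
            elif lo >= b1 and hi <= b2:
                expected = "val"
            elif lo >= b2:
                expected = "test"
            else:
                expected = None
            assert assigned == expected

    def test_no_leakage_between_split_windows(self):
        segments = [_seg("rec", s, 64) for s in range(0, 1000 - 64, 16)]
        split = time_split_target(segments, durations={"rec": 1000})
        spans = {"train": [], "val": [], "test": []}
        for seg, assigned in zip(segments, split.segment_split):
            if assigned:
                spans[assigned].append((seg.start_offset, seg.start_offset + 64))
        for (na, sa), (nb, sb) in itertools.combinations(spans.items(), 2):
            for lo_a, hi_a in sa:
                for lo_b, hi_b in sb:
                    assert hi_a <= lo_b or hi_b <= lo_a, (na, nb)

    def test_non_overlapping_windows_aligned_borders_drop_nothing(self):
        # Δω = ω and both split boundaries at multiples of ω (0.70·2000 = 1400,
        # 0.85·2000 = 1700): every segment is retained
        omega = 100
        segments = [_seg("rec", s, omega) for s in range(0, 2000, omega)]
        split = time_split_target(segments, durations={"rec": 2000})
        assert all(s is not None for s in split.segment_split)


class TestBalanceClasses:
    def _recs(self, counts, label, subject0=0):
        out = []
        for r, n in enumerate(counts):
            sid = f"{label}{subject0 + r}"
            out.append([_seg(sid, 64 * i) for i in range(n)])
        return out

    def test_worked_example_pairing(self):
        kept = balance_classes({
            "acute": self._recs([10, 4], "a"),
            "euthymia": self._recs([8, 5], "e"),
        })
        # pairs (10,8) and (4,5) -> keep 8+4 per class
        assert len(kept["acute"]) == 12 and len(kept["euthymia"]) == 12

    def test_identical_counts_drop_nothing(self):
        kept = balance_classes({
            "acute": self._recs([3, 3], "a"),
            "euthymia": self._recs([3, 3], "e"),
        })
        assert len(kept["acute"]) == len(kept["euthymia"]) == 6

    @given(counts_a=st.lists(st.integers(1, 12), min_size=1, max_size=5),
           data=st.data())
    def test_rank_pairing_minimizes_total_difference(self, counts_a, data):
        counts_b = data.draw(st.lists(st.integers(1, 12), min_size=len(counts_a),
                                      max_size=len(counts_a)))
        kept = balance_classes({
            "acute": self._recs(counts_a, "a"),
            "euthymia": self._recs(counts_b, "e"),
        })
        total_kept = len(kept["acute"])
        assert total_kept == len(kept["euthymia"])  # exact balance
        # brute force: the best pairing over all permutations keeps the most
        best = max(
            sum(min(x, y) for x, y in zip(counts_a, perm))
            for perm in itertools.permutations(counts_b)
        )
        assert total_kept == best

    def test_unequal_recording_counts_rejected(self):
        with pytest.raises(ValueError):
            balance_classes({"acute": self._recs([3], "a"),
                             "euthymia": self._recs([3, 3], "e")})

    def test_kept_segments_are_earliest(self):
        kept = balance_classes({
            "acute": self._recs([5], "a"),
            "euthymia": self._recs([3], "e"),
        })
        starts = sorted(s.start_offset for s in kept["acute"])
        assert starts == [0, 64, 128]


class TestScheduler:
    def test_ten_stale_epochs_reduce_lr(self):
        state = SchedulerState(current_lr=1e-3, best_val=1.0)
        for _ in range(9):
            state, action = scheduler_step(state, 2.0)
            assert action == "continue"
        state, action = scheduler_step(state, 2.0)
        assert action == "reduce" and state.current_lr == pytest.approx(3e-4)

    def test_improvement_resets_counter(self):
        state = SchedulerState(current_lr=1e-3, best_val=1.0)
        for _ in range(9):
            state, _ = scheduler_step(state, 2.0)
        state, action = scheduler_step(state, 0.5)  # improvement on epoch 9 of staleness
        assert action == "continue" and state.n_reductions == 0
        assert state.current_lr == 1e-3

    def test_third_reduction_terminates(self):
        state = SchedulerState(current_lr=1e-3, best_val=1.0, n_reductions=2)
        for _ in range(9):
            state, action = scheduler_step(state, 2.0)
        state, action = scheduler_step(state, 2.0)
        assert action == "stop"


class TestEvaluate:
    def test_majority_vote_subject_correct(self):
        probs = np.array([0.9, 0.8, 0.7, 0.2, 0.1])  # 3 of 5 vote acute
        labels = np.ones(5, int)
        report = evaluate(probs, labels, ["s"] * 5)
        assert report.per_subject["s"]["pred"] == 1
        assert report.acc_subject == 1.0

    def test_subject_probability_is_mean(self):
        report = evaluate(np.array([0.9, 0.2, 0.7]), np.ones(3, int), ["s"] * 3)
        assert report.per_subject["s"]["mean_prob"] == pytest.approx(0.6)

    def test_all_correct_gives_perfect_both_levels(self):
        probs = np.array([0.9, 0.9, 0.1, 0.1])
        labels = np.array([1, 1, 0, 0])
        report = evaluate(probs, labels, ["a", "a", "b", "b"])
        assert report.acc_segment == 1.0 and report.acc_subject == 1.0

    def test_tie_broken_by_mean_probability(self):
        probs = np.array([0.9, 0.4])  # one vote each; mean 0.65 -> acute
        report = evaluate(probs, np.ones(2, int), ["s", "s"])
        assert report.per_subject["s"]["pred"] == 1

    def test_majority_vote_matches_fraction_rule(self):
        """A subject is correct iff their correct-segment fraction exceeds 1/2."""
        rng = np.random.default_rng(0)
        probs = rng.random(60)
        labels = rng.integers(0, 2, size=6).repeat(10)
        subjects = [f"s{i // 10}" for i in range(60)]
        report = evaluate(probs, labels, subjects)
        for info in report.per_subject.values():
            if info["frac_correct"] > 0.5:
                assert info["pred"] == info["label"]
            elif info["frac_correct"] < 0.5:
                assert info["pred"] != info["label"]


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(5.0)
        assert pearson_corr(x, 2 * x + 1) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 1, 1], [1, 2, 3])


class TestCompareModels:
    def test_identical_models_give_corrected_p_of_one(self):
        p = np.array([0.9, 0.8, 0.7, 0.6])
        result = compare_models(p, p.copy(), ["a", "a", "b", "b"])
        assert result.degenerate
        assert result.mean_diff_segment == 0.0
        assert result.corrected["p_t_segment"] == 1.0

    def test_constant_offset_flagged_degenerate(self):
        p = np.array([0.9, 0.8, 0.7, 0.6])
        result = compare_models(p + 0.05, p, ["a", "a", "b", "b"])
        assert result.degenerate and math.isnan(result.p_t_segment)

    def test_lme_recovers_population_mean_with_coverage(self):
        """Random-intercept model covers the simulated mean ~95% of the time."""
        rng = np.random.default_rng(1)
        true_delta = 0.08
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            n_subj, n_seg = 12, 8
            subj_effect = rng.normal(0, 0.05, size=n_subj)
            diffs = true_delta + np.repeat(subj_effect, n_seg) + \
                rng.normal(0, 0.05, size=n_subj * n_seg)
            b = rng.uniform(0.2, 0.8, size=n_subj * n_seg)
            a = b + diffs
            subjects = [f"s{i // n_seg}" for i in range(n_subj * n_seg)]
            result = compare_models(a, b, subjects)
            lo, hi = result.lme_ci
            hits += int(lo <= true_delta <= hi)
        assert hits / n_rep >= 0.90
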