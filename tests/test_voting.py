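"""Metrics and iterative hard majority voting."""

import numpy as np
import pytest

from eegmotif.voting import accuracy, confusion, geometric_mean, ihmv


class TestMetrics:
    def test_perfect_predictions(self, rng):
        truth = rng.integers(1, 3, size=20)
        truth[:2] = [1, 2]  # both classes present
        cc = confusion(truth.copy(), truth)
        assert accuracy(cc) == 1.0 and geometric_mean(cc) == 1.0

    def test_hand_computed_counts(self):
        # tp=9 fn=2 tn=8 fp=1 laid out explicitly
        truth = np.array([2] * 11 + [1] * 9)
        pred = np.array([2] * 9 + [1] * 2 + [1] * 8 + [2] * 1)
        cc = confusion(pred, truth)
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (9, 2, 8, 1)
        assert accuracy(cc) == pytest.approx(0.85)
        assert geometric_mean(cc) == pytest.approx(np.sqrt((9 / 11) * (8 / 9)))

    def test_one_class_fully_missed_zeroes_gm(self):
        truth = np.array([1, 1, 2, 2])
        pred = np.array([1, 1, 1, 1])
        cc = confusion(pred, truth)
        assert accuracy(cc) == 0.5
        assert geometric_mean(cc) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion(np.array([1, 2]), np.array([1, 2, 1]))

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            confusion(np.array([1, 1]), np.array([1, 1]))


def oracle_mode(stack, record):
    counts = {}
    for row in stack:
        lab = int(row[record])
        counts[lab] = counts.get(lab, 0) + 1
    return max(counts, key=lambda lab: (counts[lab], -lab))


class TestIHMV:
    def _random_instance(self, seed, C=14, n=40):
        rng = np.random.default_rng(seed)
        truth = rng.integers(1, 3, size=n)
        truth[:2] = [1, 2]
        preds = [np.where(rng.random(n) < 0.7, truth, 3 - truth) for _ in range(C)]
        return preds, truth

    def test_fourteen_channels_give_twelve_voted(self):
        preds, truth = self._random_instance(0)
        voted, report = ihmv(preds, truth)
        assert len(voted) == 12
        assert len(report.voted_accuracy) == 12
        assert len(report.channel_accuracy) == 14

    @pytest.mark.parametrize("C", [3, 5, 9])
    def test_voted_count_is_channels_minus_two(self, C):
        preds, truth = self._random_instance(1, C=C)
        voted, _ = ihmv(preds, truth)
        assert len(voted) == C - 2

    def test_unanimous_channels(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(1, 3, size=30)
        truth[:2] = [1, 2]
        one = np.where(rng.random(30) < 0.8, truth, 3 - truth)
        voted, report = ihmv([one.copy() for _ in range(14)], truth)
        for v in voted:
            np.testing.assert_array_equal(v.labels, one)
        assert report.final_accuracy == pytest.approx(np.mean(one == truth))

    def test_final_at_least_best_channel(self):
        for seed in range(5):
            preds, truth = self._random_instance(seed)
            _, report = ihmv(preds, truth)
            assert report.final_accuracy >= max(report.channel_accuracy)

    def test_mode_matches_brute_force(self):
        for seed in range(10):
            preds, truth = self._random_instance(seed, C=7)
            voted, report = ihmv(preds, truth)
            mat = np.stack(preds)
            for r, v in zip(range(3, 8), voted):
                stack = mat[report.channel_order[:r]]
                expected = [oracle_mode(stack, i) for i in range(len(truth))]
                np.testing.assert_array_equal(v.labels, expected)

    def test_strict_majority_wins_each_record(self):
        preds, truth = self._random_instance(3)
        voted, report = ihmv(preds, truth)
        mat = np.stack(preds)
        for r, v in zip(range(3, 15), voted):
            stack = mat[report.channel_order[:r]]
            for i in range(len(truth)):
                votes = stack[:, i]
                for lab in (1, 2):
                    if np.sum(votes == lab) * 2 > r:
                        assert v.labels[i] == lab

    def test_fewer_than_three_vectors_rejected(self):
        preds, truth = self._random_instance(0, C=2)
        with pytest.raises(ValueError, match="at least 3"):
            ihmv(preds, truth)

    def test_mode_tie_prefers_smaller_label(self):
        truth = np.array([1, 2, 1, 2])
        a = np.array([1, 1, 1, 1])
        b = np.array([2, 2, 2, 2])
        c = np.array([1, 2, 1, 2])
        d = np.array([2, 1, 2, 1])
        voted, _ = ihmv([a, b, c, d], truth)
        # r=4 stack is a 2-2 tie on every record -> label 1 everywhere
        np.testing.assert_array_equal(voted[-1].labels, 1)
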