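import numpy as np
import pytest

from docknet.benchmark_eval import (
    ConfusionCounts,
    LabeledPair,
    LabeledPairSet,
    calibrate_threshold,
    confusion_at_threshold,
    f_measure,
    metrics,
    roc_auc,
    shuffle_negatives,
)
from oracles import auc_pair_counting


def labeled(pos_z, neg_z):
    return LabeledPairSet.from_scores(pos_z, neg_z)


class TestShuffleNegatives:
    def test_requested_count(self):
        positives = [(f"A{i}", f"B{i}") for i in range(30)]
        negs = shuffle_negatives(positives, n_neg=300, seed=0)
        assert len(negs) == 300
        assert len(set(negs)) == 300

    def test_zero(self):
        assert shuffle_negatives([("A", "B")], n_neg=0, seed=0) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_single_pair_enumeration(self, seed):
        # over {A,B,C,D} with positive (A,B), admissible negatives are known
        positives = [("A", "B"), ("C", "D")]
        negs = shuffle_negatives(positives, n_neg=1, seed=seed)
        assert negs[0] in {("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")}

    def test_never_intersects_positives(self):
        positives = [(f"A{i}", f"B{i}") for i in range(20)]
        for seed in range(5):
            negs = shuffle_negatives(positives, n_neg=100, seed=seed)
            assert not set(negs) & {tuple(sorted(p)) for p in positives}
            assert all(a != b for a, b in negs)

    def test_excess_request_errors(self):
        with pytest.raises(ValueError, match="admissible"):
            shuffle_negatives([("A", "B")], n_neg=10, seed=0)

    def test_deterministic(self):
        positives = [(f"A{i}", f"B{i}") for i in range(10)]
        assert shuffle_negatives(positives, 50, seed=3) == shuffle_negatives(positives, 50, seed=3)


class TestConfusion:
    def test_all_positive_below_min(self):
        lps = labeled([9, 5], [6, 2, 1])
        c = confusion_at_threshold(lps, -100.0)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 3, 0, 0)

    def test_all_negative_above_max(self):
        lps = labeled([9, 5], [6, 2, 1])
        c = confusion_at_threshold(lps, 100.0)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 3, 2)

    def test_hand_count_at_8_8(self):
        lps = labeled([9, 9, 5], [6, 2, 1])
        c = confusion_at_threshold(lps, 8.8)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 3, 1)

    def test_partition_invariant(self):
        lps = labeled([9, 9, 5], [6, 2, 1])
        for t in (-1, 3, 8.8, 42):
            c = confusion_at_threshold(lps, t)
            assert c.n_pos == 3 and c.n_neg == 3


class TestMetrics:
    def test_balanced_degenerate_row(self):
        m = metrics(ConfusionCounts(tp=588, fp=588, tn=0, fn=0))
        assert (m.precision, m.tpr) == (0.5, 1.0)
        assert round(m.f_measure, 4) == 0.6667

    def test_1_to_100_row(self):
        # counts consistent with TPR 0.1003, FPR 0.0031, precision 0.2458
        m = metrics(ConfusionCounts(tp=59, fp=181, tn=58619, fn=529))
        assert round(m.tpr, 4) == 0.1003
        assert round(m.fpr, 4) == 0.0031
        assert round(m.precision, 4) == 0.2458
        assert round(m.f_measure, 4) == 0.1425

    def test_zero_predictions_warns_precision_zero(self):
        with pytest.warns(UserWarning, match="precision"):
            m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert m.precision == 0.0
        assert m.f_measure == 0.0

    def test_f_zero_when_tp_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=3, tn=2, fn=5))
        assert (m.precision, m.tpr, m.f_measure) == (0.0, 0.0, 0.0)

    def test_needs_positives(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(tp=0, fp=1, tn=1, fn=0))


class TestFMeasure:
    @pytest.mark.parametrize("p,r,expected", [
        (0.5000, 1.0000, 0.6667),
        (0.2185, 0.2245, 0.2215),
        (0.2458, 0.1003, 0.1425),
    ])
    def test_published_rows(self, p, r, expected):
        assert round(f_measure(p, r), 4) == expected

    def test_zero_convention(self):
        assert f_measure(0.0, 0.0) == 0.0


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(labeled([5, 6, 7], [1, 2, 3])).auc == pytest.approx(1.0)

    def test_all_tied(self):
        assert roc_auc(labeled([4, 4], [4, 4, 4])).auc == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc(labeled([1, 2], []))

    def test_curve_endpoints_and_monotone_fpr(self):
        rng = np.random.default_rng(5)
        lps = labeled(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        curve = roc_auc(lps)
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)
        fprs = [p[0] for p in curve.points]
        assert all(a <= b for a, b in zip(fprs, fprs[1:]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(1, 25))
        n_neg = int(rng.integers(1, 25))
        # half-integer grid forces plenty of ties
        pos = (rng.integers(0, 8, n_pos) / 2).tolist()
        neg = (rng.integers(0, 8, n_neg) / 2).tolist()
        assert roc_auc(labeled(pos, neg)).auc == pytest.approx(
            auc_pair_counting(pos, neg), abs=1e-12
        )


class TestCalibrate:
    def test_overlapping_balanced_set_degenerates_to_all_positive(self):
        # maximal overlap: identical score distributions in both classes —
        # the F-optimum is the all-positive decision, exactly the published
        # balanced-ratio calibration row
        rng = np.random.default_rng(8)
        pos = rng.normal(6.6, 1.5, 588)
        neg = pos.copy()
        t, m, sweep = calibrate_threshold(labeled(pos, neg))
        assert t == pytest.approx(min(np.concatenate([pos, neg])))
        assert (round(m.tpr, 4), round(m.fpr, 4)) == (1.0, 1.0)
        assert round(m.precision, 4) == 0.5
        assert round(m.f_measure, 4) == 0.6667

    def test_perfect_separation_reaches_f1(self):
        t, m, _ = calibrate_threshold(labeled([8, 9, 10], [1, 2, 3]))
        assert m.f_measure == pytest.approx(1.0)
        assert t == pytest.approx(8.0)

    def test_tie_break_toward_largest_threshold(self):
        # thresholds 5 and 7 both give perfect F; the larger must win
        t, m, _ = calibrate_threshold(labeled([7.0, 9.0], [1.0, 2.0]),
                                      candidates=[5.0, 7.0])
        assert t == 7.0

    def test_sweep_table_columns(self):
        _, _, sweep = calibrate_threshold(labeled([5, 6], [1, 2]))
        assert list(sweep.columns) == ["threshold", "tpr", "fpr", "precision", "f_measure"]

    @pytest.mark.parametrize("seed", range(10))
    def test_imbalance_pushes_threshold_up_and_fpr_down(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(6.6, 1.5, 60)
        neg_all = rng.normal(5.9, 1.5, 6000)
        results = {}
        for ratio in (1, 10, 100):
            lps = labeled(pos, neg_all[: 60 * ratio])
            t, m, _ = calibrate_threshold(lps)
            results[ratio] = (t, m.fpr)
        assert results[100][0] > results[1][0]
        assert results[1][1] >= results[10][1] >= results[100][1]
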