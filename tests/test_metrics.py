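"""Detection metrics: matching, ratios, AP/mAP, image-level counts."""

import itertools
import warnings

import numpy as np
import pytest

from lesiondet.boxgeom import Box
from lesiondet.metrics import (ConfusionCounts, GroundTruth, PRCurve,
                               accuracy, ap_at_threshold, average_precision,
                               aggregate_reports, evaluate_detections,
                               image_level_counts, map50, map50_95,
                               match_detections, mean_ap, precision, recall,
                               specificity)
from lesiondet.model import Detection

from _oracles import ap_by_cutoff_enumeration


def det(x1, y1, x2, y2, cls=0, conf=0.9):
    return Detection(Box(x1, y1, x2, y2), cls, conf)


def gt(x1, y1, x2, y2, cls=0):
    return GroundTruth(Box(x1, y1, x2, y2), cls)


class TestMatching:
    def test_exact_hit(self):
        counts, matches = match_detections([det(0, 0, 10, 10)], [gt(0, 0, 10, 10)], 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)
        assert matches == [(0, 0)]

    def test_double_detection_counts_one_fp(self):
        counts, _ = match_detections(
            [det(0, 0, 10, 10, conf=0.9), det(1, 1, 11, 11, conf=0.8)],
            [gt(0, 0, 10, 10)], 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)

    def test_class_mismatch_never_matches(self):
        counts, _ = match_detections([det(0, 0, 10, 10, cls=1)], [gt(0, 0, 10, 10, cls=2)], 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)

    def test_invalid_threshold_rejected(self):
        for thr in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                match_detections([], [], thr)

    @pytest.mark.parametrize("trial", range(20))
    def test_tp_count_matches_exhaustive_assignment_oracle(self, trial):
        """Greedy matching with distinct confidences finds as many true
        positives as the best one-to-one assignment."""
        rng = np.random.default_rng(trial)
        n_det, n_gt = rng.integers(1, 5), rng.integers(1, 4)
        dets, gts = [], []
        for i in range(n_det):
            x, y = rng.uniform(0, 30, 2)
            w, h = rng.uniform(5, 20, 2)
            dets.append(det(x, y, x + w, y + h, conf=0.5 + 0.4 * i / n_det))
        for _ in range(n_gt):
            x, y = rng.uniform(0, 30, 2)
            w, h = rng.uniform(5, 20, 2)
            gts.append(gt(x, y, x + w, y + h))
        thr = 0.3
        counts, _ = match_detections(dets, gts, thr)
        # brute force: best number of disjoint det-gt pairs with IoU >= thr
        from lesiondet.boxgeom import iou
        best = 0
        for k in range(min(n_det, n_gt), 0, -1):
            for dsel in itertools.permutations(range(n_det), k):
                for gsel in itertools.combinations(range(n_gt), k):
                    ok = all(iou(dets[d].box, gts[g].box) >= thr
                             for d, g in zip(dsel, gsel))
                    if ok:
                        best = max(best, k)
                if best == k:
                    break
            if best:
                break
        assert counts.tp == best


class TestRatios:
    def test_worked_examples(self):
        assert precision(ConfusionCounts(tp=9, fp=1)) == pytest.approx(0.9)
        assert recall(ConfusionCounts(tp=9, fn=3)) == pytest.approx(0.75)
        c = ConfusionCounts(tp=50, tn=40, fp=5, fn=5)
        assert accuracy(c) == pytest.approx(0.9)
        assert specificity(c) == pytest.approx(40 / 45)

    def test_zero_denominator_warns_and_returns_zero(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            assert precision(ConfusionCounts()) == 0.0
        assert any("zero denominator" in str(w.message) for w in caught)


class TestAveragePrecision:
    def test_perfect_and_empty(self):
        curve = PRCurve.from_flags([0.9, 0.8], [1, 1], num_gt=2)
        assert average_precision(curve) == pytest.approx(1.0)
        assert average_precision(PRCurve(np.array([]), np.array([]))) == 0.0
        none = PRCurve.from_flags([0.9, 0.8], [0, 0], num_gt=2)
        assert average_precision(none) == 0.0

    def test_three_detection_hand_case_matches_cutoff_oracle(self):
        # 2 ground truths; hits at conf .9 and .7, a miss at .8
        confs, flags = [0.9, 0.8, 0.7], [1, 0, 1]
        ap = average_precision(PRCurve.from_flags(confs, flags, num_gt=2))
        oracle = ap_by_cutoff_enumeration(confs, flags, 2)
        # hand sweep: (R=.5, P=1), (R=.5, P=.5), (R=1, P=2/3)
        assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3), abs=1e-12)
        assert ap == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("trial", range(30))
    def test_equals_cutoff_enumeration_on_small_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(1, 11))
        confs = rng.choice(np.linspace(0.05, 0.95, 50), size=n, replace=False)
        flags = rng.integers(0, 2, size=n)
        num_gt = int(flags.sum() + rng.integers(0, 3))
        if num_gt == 0:
            return
        ap = average_precision(PRCurve.from_flags(confs, flags, num_gt))
        assert ap == pytest.approx(ap_by_cutoff_enumeration(confs, flags, num_gt),
                                   abs=1e-12)

    def test_detection_order_never_changes_metrics(self, rng):
        dets = [det(i * 5, 0, i * 5 + 8, 8, cls=i % 2, conf=0.3 + 0.05 * i)
                for i in range(8)]
        gts = [gt(i * 5 + 1, 0, i * 5 + 8, 8, cls=i % 2) for i in range(6)]
        base = ap_at_threshold([dets], [gts], 0.5, 0)
        for _ in range(5):
            shuffled = list(dets)
            rng.shuffle(shuffled)
            assert ap_at_threshold([shuffled], [gts], 0.5, 0) == pytest.approx(base)

    def test_ap_monotone_non_increasing_in_iou_threshold(self):
        dets = [det(0, 0, 10, 10, conf=0.9), det(20, 20, 28, 31, conf=0.7)]
        gts = [gt(1, 1, 11, 11), gt(21, 20, 29, 30)]
        aps = [ap_at_threshold([dets], [gts], t, 0)
               for t in (0.5, 0.6, 0.7, 0.8, 0.9)]
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))


class TestMeanAP:
    def test_unweighted_mean_and_single_class(self):
        assert mean_ap([1.0, 0.5]) == pytest.approx(0.75)
        assert mean_ap([0.62]) == pytest.approx(0.62)

    def test_map50_dominates_map50_95(self, rng):
        dets, gts = [], []
        for i in range(6):
            x, y = rng.uniform(0, 40, 2)
            w, h = rng.uniform(8, 20, 2)
            gts.append([gt(x, y, x + w, y + h, cls=i % 3)])
            dets.append([det(x + 2, y + 1, x + w + 1, y + h - 1, cls=i % 3,
                             conf=0.5 + 0.05 * i)])
        assert map50(dets, gts) >= map50_95(dets, gts) - 1e-12


class TestImageLevel:
    def test_lesion_image_correct_class(self):
        counts = image_level_counts([[det(0, 0, 5, 5, cls=2)]], [{2}], 4)
        assert counts[2].tp == 1
        for c in (0, 1, 3):
            assert counts[c].tn == 1

    def test_clean_image_no_detections_all_tn(self):
        counts = image_level_counts([[]], [set()], 4)
        assert all(counts[c].tn == 1 for c in range(4))

    def test_two_image_two_class_enumeration(self):
        # image A: true {0}, predicted {0, 1}; image B: true {1}, predicted {}
        dets = [[det(0, 0, 5, 5, cls=0), det(9, 9, 14, 14, cls=1)], []]
        counts = image_level_counts(dets, [{0}, {1}], 2)
        assert (counts[0].tp, counts[0].fp, counts[0].fn, counts[0].tn) == (1, 0, 0, 1)
        assert (counts[1].tp, counts[1].fp, counts[1].fn, counts[1].tn) == (0, 1, 1, 0)


class TestReporting:
    def test_perfect_oracle_detections_score_one(self):
        gts = [[gt(5, 5, 20, 20, cls=c)] for c in range(4)]
        dets = [[det(5, 5, 20, 20, cls=c, conf=0.99)] for c in range(4)]
        report = evaluate_detections(dets, gts, 4)
        assert report.map50 == pytest.approx(1.0)
        assert report.map50_95 == pytest.approx(1.0)
        for c in range(4):
            assert report.per_class[c]["precision"] == 1.0
            assert report.per_class[c]["recall"] == 1.0
            assert report.per_class[c]["accuracy"] == 1.0

    def test_fold_aggregation_matches_direct_recomputation(self):
        gts = [[gt(5, 5, 20, 20, cls=0)]]
        r1 = evaluate_detections([[det(5, 5, 20, 20, cls=0, conf=0.9)]], gts, 2)
        r2 = evaluate_detections([[det(50, 50, 60, 60, cls=0, conf=0.9)]], gts, 2)
        table = aggregate_reports([r1, r2])
        got = table.loc["class_0", "precision"]
        want = np.mean([r1.per_class[0]["precision"], r2.per_class[0]["precision"]])
        assert got == pytest.approx(want)
        sd = table.loc["class_0", "precision_sd"]
        assert sd == pytest.approx(np.std([r1.per_class[0]["precision"],
                                           r2.per_class[0]["precision"]], ddof=1))
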