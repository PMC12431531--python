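"""mAP / confusion-matrix machinery against a brute-force PR oracle."""

import itertools

import numpy as np
import pytest

from pigstressnet.evaluate import average_precision, evaluate, nms
from pigstressnet.losses import iou as box_iou


def det(box, cls, conf):
    return {"box": np.asarray(box, dtype=float), "cls": cls, "conf": conf}


def gt(box, cls):
    return {"box": np.asarray(box, dtype=float), "cls": cls}


def brute_force_ap(records, n_gt, n_points=101):
    """Independent oracle: enumerate the PR curve point by point."""
    records = sorted(records, key=lambda r: -r[0])
    aps = []
    for level in np.linspace(0, 1, n_points):
        best = 0.0
        for k in range(1, len(records) + 1):
            tp = sum(r[1] for r in records[:k])
            recall = tp / n_gt
            precision = tp / k
            if recall >= level:
                best = max(best, precision)
        aps.append(best)
    return float(np.mean(aps))


class TestAveragePrecision:
    def test_matches_brute_force_on_hand_case(self):
        # 3 GT; detections: TP, FP, TP, TP, FP (confidence-descending)
        tp = np.array([1.0, 0.0, 1.0, 1.0, 0.0])
        conf = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        ap, _, _ = average_precision(tp, conf, n_gt=3)
        oracle = brute_force_ap(list(zip(conf, tp)), 3)
        assert ap == pytest.approx(oracle, abs=1e-12)

    def test_random_cases_match_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 12))
            tp = rng.integers(0, 2, n).astype(float)
            conf = rng.uniform(size=n)
            n_gt = max(int(tp.sum()), int(rng.integers(1, 6)))
            ap, _, _ = average_precision(tp, conf, n_gt)
            assert ap == pytest.approx(brute_force_ap(list(zip(conf, tp)), n_gt),
                                       abs=1e-12)


class TestEvaluate:
    def test_perfect_predictions(self):
        gts = [[gt([0, 0, 10, 10], 0), gt([20, 20, 40, 40], 3)]]
        preds = [[det([0, 0, 10, 10], 0, 0.9), det([20, 20, 40, 40], 3, 0.8)]]
        res = evaluate(preds, gts)
        assert res.map50 == pytest.approx(1.0)
        conf = res.confusion
        assert conf[0, 0] == 1 and conf[3, 3] == 1
        assert conf.sum() == 2
        # normalised rows of occupied classes sum to one
        norm = res.normalized_confusion()
        assert norm[0].sum() == pytest.approx(1.0)

    def test_no_predictions(self):
        gts = [[gt([0, 0, 10, 10], 2)]]
        res = evaluate([[]], gts)
        assert res.map50 == 0.0
        assert res.confusion[2, 5] == 1   # background column

    def test_localization_miss_and_false_positive(self):
        # hand-worked: 2 GT of class 0; one good hit, one poor-IoU miss,
        # plus one confident false positive
        gts = [[gt([0, 0, 10, 10], 0), gt([50, 50, 60, 60], 0)]]
        preds = [[det([0, 0, 10, 10], 0, 0.9),
                  det([70, 70, 80, 80], 0, 0.8),
                  det([50, 58, 60, 68], 0, 0.7)]]   # IoU 1/9 with 2nd gt
        res = evaluate(preds, gts)
        oracle = brute_force_ap([(0.9, 1.0), (0.8, 0.0), (0.7, 0.0)], 2)
        assert res.per_class_ap[0] == pytest.approx(oracle, abs=1e-12)

    def test_order_invariance_at_equal_confidence(self):
        g = [[gt([0, 0, 10, 10], 0), gt([30, 30, 44, 44], 0)]]
        p1 = [[det([0, 0, 10, 10], 0, 0.5), det([30, 30, 44, 44], 0, 0.5)]]
        p2 = [[det([30, 30, 44, 44], 0, 0.5), det([0, 0, 10, 10], 0, 0.5)]]
        r1 = evaluate(p1, g)
        r2 = evaluate(p2, g)
        assert r1.map50 == r2.map50 == pytest.approx(1.0)

    def test_confusion_conserves_ground_truth_count(self, rng):
        gts, preds = [], []
        for i in range(10):
            n = int(rng.integers(0, 5))
            img_gts = [gt([x1 := rng.uniform(0, 80), y1 := rng.uniform(0, 80),
                           x1 + rng.uniform(5, 20), y1 + rng.uniform(5, 20)],
                          int(rng.integers(0, 5))) for _ in range(n)]
            img_preds = [det([x1 := rng.uniform(0, 80), y1 := rng.uniform(0, 80),
                              x1 + rng.uniform(5, 20), y1 + rng.uniform(5, 20)],
                             int(rng.integers(0, 5)), rng.uniform())
                         for _ in range(int(rng.integers(0, 5)))]
            gts.append(img_gts)
            preds.append(img_preds)
        res = evaluate(preds, gts)
        total_gt = sum(len(g) for g in gts)
        # each ground truth lands in exactly one row entry
        assert res.confusion[:5, :].sum() == total_gt

    def test_misclassified_match_fills_off_diagonal(self):
        gts = [[gt([0, 0, 10, 10], 3)]]
        preds = [[det([0, 0, 10, 10], 4, 0.9)]]
        res = evaluate(preds, gts)
        assert res.confusion[3, 4] == 1


class TestNMS:
    def test_removes_lower_scoring_overlap(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [30, 30, 40, 40]],
                         dtype=float)
        scores = np.array([0.9, 0.8, 0.7])
        keep = nms(boxes, scores, iou_thr=0.45)
        assert set(keep.tolist()) == {0, 2}
        assert box_iou(boxes[0], boxes[1]) > 0.45

    def test_empty(self):
        assert nms(np.zeros((0, 4)), np.zeros(0)).size == 0
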