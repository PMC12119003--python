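"""Detection metrics vs hand-worked examples and independent oracles."""

import numpy as np
import pytest

from lesiondet.metrics import (
    BoxGT,
    BoxPred,
    EvalCounts,
    average_precision,
    confusion_matrix,
    evaluate_detections,
    iou,
    map50_95,
    match_detections,
    precision,
    recall,
    write_report_csv,
)

from oracles import ap_all_cutoff, ap_cocostyle


def P(img, cls, conf, box):
    return BoxPred(img, cls, conf, box)


def G(img, cls, box):
    return BoxGT(img, cls, box)


def _random_fixture(seed, n_img=4, n_cls=3):
    """Random predictions and ground truth over a few images/classes."""
    rng = np.random.default_rng(seed)
    gts, preds = [], []
    for img in range(n_img):
        for _ in range(rng.integers(1, 4)):
            x, y = rng.uniform(0, 60, 2)
            w, h = rng.uniform(8, 30, 2)
            cls = int(rng.integers(0, n_cls))
            gts.append(G(img, cls, (x, y, x + w, y + h)))
    for g in gts:
        for _ in range(rng.integers(0, 3)):
            jitter = rng.normal(0, 6, 4)
            b = np.array(g.box) + jitter
            cls = g.class_id if rng.random() < 0.8 else int(rng.integers(0, n_cls))
            preds.append(P(g.image_id, cls, float(rng.uniform(0.05, 1)),
                           tuple(b)))
    for _ in range(5):  # pure false positives
        x, y = rng.uniform(0, 60, 2)
        preds.append(P(int(rng.integers(0, n_img)), int(rng.integers(0, n_cls)),
                       float(rng.uniform(0.05, 1)), (x, y, x + 10, y + 10)))
    return preds, gts


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_partial_overlap_rectangle_arithmetic(self):
        assert iou((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_degenerate_box_gives_zero(self):
        assert iou((1, 1, 1, 1), (0, 0, 2, 2)) == 0.0


class TestMatching:
    def test_exact_hit(self):
        c, _ = match_detections([P(0, 1, 0.9, (0, 0, 10, 10))],
                                [G(0, 1, (0, 0, 10, 10))], 0.5)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_double_prediction_single_gt(self):
        c, matches = match_detections(
            [P(0, 1, 0.9, (0, 0, 10, 10)), P(0, 1, 0.8, (1, 0, 11, 10))],
            [G(0, 1, (0, 0, 10, 10))], 0.5)
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)
        assert matches == [(0, 0)]  # higher confidence wins

    def test_wrong_class_overlap(self):
        c, _ = match_detections([P(0, 2, 0.9, (0, 0, 10, 10))],
                                [G(0, 1, (0, 0, 10, 10))], 0.5)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    @pytest.mark.parametrize("seed", range(4))
    def test_tp_plus_fn_equals_gt_count(self, seed):
        preds, gts = _random_fixture(seed)
        for thr in (0.5, 0.75):
            c, _ = match_detections(preds, gts, thr)
            assert c.tp + c.fn == len(gts)


class TestPrecisionRecall:
    def test_printed_formula_cases(self):
        assert precision(EvalCounts(tp=3, fp=1)) == 0.75
        assert recall(EvalCounts(tp=3, fn=3)) == 0.5

    def test_empty_denominator_conventions(self):
        assert precision(EvalCounts()) == 1.0
        assert recall(EvalCounts()) == 1.0


class TestAveragePrecision:
    def test_single_confident_hit_is_perfect(self):
        assert average_precision([P(0, 0, 0.9, (0, 0, 10, 10))],
                                 [G(0, 0, (0, 0, 10, 10))]) == pytest.approx(1.0)

    def test_no_predictions_is_zero(self):
        assert average_precision([], [G(0, 0, (0, 0, 10, 10))]) == 0.0

    def test_toy_mixed_set_matches_all_cutoff_oracle(self):
        gts = [G(0, 0, (0, 0, 10, 10)), G(0, 0, (20, 20, 30, 30))]
        preds = [
            P(0, 0, 0.9, (0, 0, 10, 10)),      # hit
            P(0, 0, 0.7, (50, 50, 60, 60)),    # miss
            P(0, 0, 0.5, (20, 20, 30, 30)),    # hit
        ]
        got = average_precision(preds, gts, 0.5)
        assert got == pytest.approx(ap_all_cutoff(preds, gts, 0.5), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_fixtures_match_both_independent_oracles(self, seed):
        preds, gts = _random_fixture(seed)
        for cls in {g.class_id for g in gts}:
            pc = [p for p in preds if p.class_id == cls]
            gc = [g for g in gts if g.class_id == cls]
            mine = average_precision(pc, gc, 0.5)
            assert mine == pytest.approx(ap_cocostyle(pc, gc, 0.5), abs=0.01)
            assert mine == pytest.approx(ap_all_cutoff(pc, gc, 0.5), abs=0.01)

    def test_invariant_to_monotone_confidence_transform(self):
        preds, gts = _random_fixture(7)
        squeezed = [BoxPred(p.image_id, p.class_id, 0.1 + 0.8 * p.confidence**3, p.box)
                    for p in preds]
        for cls in range(3):
            pc = [p for p in preds if p.class_id == cls]
            sc = [p for p in squeezed if p.class_id == cls]
            gc = [g for g in gts if g.class_id == cls]
            if gc:
                assert average_precision(pc, gc) == pytest.approx(
                    average_precision(sc, gc), abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_strict_iou_average_never_exceeds_map50(self, seed):
        preds, gts = _random_fixture(seed)
        m50 = np.nanmean([
            average_precision([p for p in preds if p.class_id == c],
                              [g for g in gts if g.class_id == c], 0.5)
            for c in range(3)
            if any(g.class_id == c for g in gts)])
        m5095 = map50_95(preds, gts, 3)
        assert m5095 <= m50 + 1e-9


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        gts = [G(0, 0, (0, 0, 10, 10)), G(0, 1, (20, 0, 30, 10))]
        preds = [P(0, 0, 0.9, (0, 0, 10, 10)), P(0, 1, 0.9, (20, 0, 30, 10))]
        mat = confusion_matrix(preds, gts, 2)
        assert mat[0, 0] == 1 and mat[1, 1] == 1
        assert mat.sum() == 2

    def test_all_below_threshold_only_background_row(self):
        gts = [G(0, 0, (0, 0, 10, 10))]
        preds = [P(0, 0, 0.1, (0, 0, 10, 10))]
        mat = confusion_matrix(preds, gts, 2, conf_thr=0.25)
        assert mat[2, 0] == 1 and mat.sum() == 1

    def test_crafted_four_object_example(self):
        gts = [
            G(0, 0, (0, 0, 10, 10)),
            G(0, 1, (20, 0, 30, 10)),
            G(0, 1, (40, 0, 50, 10)),
            G(1, 0, (0, 0, 10, 10)),
        ]
        preds = [
            P(0, 0, 0.9, (0, 0, 10, 10)),     # correct class 0
            P(0, 0, 0.8, (20, 0, 30, 10)),    # class confusion: predicts 0 on gt 1
            P(0, 1, 0.7, (70, 0, 80, 10)),    # false positive
            # gt (40,0) and the image-1 gt are missed
        ]
        mat = confusion_matrix(preds, gts, 2)
        expected = np.zeros((3, 3), int)
        expected[0, 0] = 1   # correct
        expected[0, 1] = 1   # predicted 0, truth 1
        expected[1, 2] = 1   # unmatched prediction of class 1 -> background
        expected[2, 1] = 1   # missed class-1 gt
        expected[2, 0] = 1   # missed class-0 gt (image 1)
        assert np.array_equal(mat, expected)


class TestSummary:
    def test_report_rows_and_csv(self, tmp_path):
        preds, gts = _random_fixture(1)
        summary = evaluate_detections(preds, gts, ["a", "b", "c"])
        rows = list(summary.rows())
        assert rows[0][0] == "all" and len(rows) == 4
        assert 0.0 <= summary.map50 <= 1.0
        out = tmp_path / "report.csv"
        write_report_csv(summary, out)
        header = out.read_text().splitlines()[0]
        assert header == "Class,Instances,P,R,mAP50,mAP50-95"
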