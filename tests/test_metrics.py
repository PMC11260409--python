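"""Evaluation metrics: printed formulas, AP oracles, COCO conventions."""

import numpy as np
import pytest

from voidspot.io_formats import instances_to_annotations, rle_encode
from voidspot.metrics import (
    AREA_BANDS,
    COCO_IOU_THRESHOLDS,
    EvalCounts,
    PRCurve,
    ap_at,
    ap_at_dataset,
    area_stratified_ap,
    average_precision,
    build_pr_curve,
    coco_ap,
    match_instances,
    mean_average_precision,
    precision_recall_f1,
)

from conftest import disc_instance, disc_mask, random_instances
from reference_eval import brute_force_ap_exact, ref_evaluate

SHAPE = (100, 100)


def square_instance(r0, c0, size, shape=SHAPE, score=1.0):
    mask = np.zeros(shape, bool)
    mask[r0 : r0 + size, c0 : c0 + size] = True
    from voidspot.instances import SpotInstance

    return SpotInstance(mask=mask, score=score)


class TestMatchInstances:
    def test_perfect_predictions(self):
        truths = [disc_instance(SHAPE, (30, 30), 10), disc_instance(SHAPE, (70, 60), 8)]
        preds = [disc_instance(SHAPE, (30, 30), 10, 0.9), disc_instance(SHAPE, (70, 60), 8, 0.8)]
        counts, flags = match_instances(preds, truths)
        assert (counts.tp, counts.fp, counts.fn) == (2, 0, 0)
        assert flags == [True, True]

    def test_no_predictions_all_false_negatives(self):
        truths = [disc_instance(SHAPE, (30, 30), 10)]
        counts, _ = match_instances([], truths)
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 1)

    def test_duplicate_prediction_counts_as_false_positive(self):
        truths = [disc_instance(SHAPE, (30, 30), 10), disc_instance(SHAPE, (70, 60), 8)]
        preds = [
            disc_instance(SHAPE, (30, 30), 10, 0.9),
            disc_instance(SHAPE, (31, 30), 10, 0.7),  # duplicate over truth 0, IoU ~0.8
            disc_instance(SHAPE, (70, 60), 8, 0.8),
        ]
        counts, flags = match_instances(preds, truths, iou_threshold=0.5)
        assert (counts.tp, counts.fp, counts.fn) == (2, 1, 0)
        assert flags == [True, False, True]


class TestPrintedFormulas:
    def test_hand_computed_case(self):
        p, r, f1 = precision_recall_f1(EvalCounts(tp=3, fp=1, fn=3))
        assert (p, r, f1) == (75.0, 50.0, 60.0)

    def test_all_correct(self):
        assert precision_recall_f1(EvalCounts(5, 0, 0)) == (100.0, 100.0, 100.0)

    def test_degenerate_zero_counts(self):
        assert precision_recall_f1(EvalCounts(0, 0, 0)) == (0.0, 0.0, 0.0)

    def test_f1_is_harmonic_mean_fixed_point(self):
        # P == R implies F1 == P
        p, r, f1 = precision_recall_f1(EvalCounts(tp=4, fp=2, fn=2))
        assert p == r == f1

    def test_exhaustive_small_count_grid(self):
        for tp in range(0, 21):
            for fp in range(0, 21):
                for fn in range(0, 21):
                    p, r, f1 = precision_recall_f1(EvalCounts(tp, fp, fn))
                    ep = 100.0 * tp / (tp + fp) if tp + fp else 0.0
                    er = 100.0 * tp / (tp + fn) if tp + fn else 0.0
                    ef = 2 * ep * er / (ep + er) if ep + er else 0.0
                    assert p == pytest.approx(ep) and r == pytest.approx(er)
                    assert f1 == pytest.approx(ef)
                    assert 0 <= p <= 100 and 0 <= r <= 100 and 0 <= f1 <= 100


class TestAveragePrecision:
    def test_single_hit_gives_unit_ap(self):
        curve = build_pr_curve([True], [0.9], n_truth=1)
        assert average_precision(curve) == pytest.approx(1.0)
        assert average_precision(curve, "exact") == pytest.approx(1.0)

    def test_all_misses_give_zero_ap(self):
        curve = build_pr_curve([False, False], [0.9, 0.8], n_truth=2)
        assert average_precision(curve) == 0.0
        assert average_precision(curve, "exact") == 0.0

    def test_hit_miss_hit_matches_step_integral(self):
        # ranked flags (TP, FP, TP), 2 truths:
        # TP1: P=1, R=0.5 ; FP: P=2/3 ; TP2: P=2/3, R=1.0
        curve = build_pr_curve([True, False, True], [0.9, 0.8, 0.7], n_truth=2)
        assert average_precision(curve, "exact") == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_undefined_without_truth(self):
        with pytest.raises(ValueError):
            average_precision(PRCurve(np.array([]), np.array([]), n_truth=0))

    def test_score_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        truths = random_instances(rng, SHAPE, 5, with_scores=False)
        preds = random_instances(rng, SHAPE, 7)
        base = ap_at(preds, truths, 0.5)
        squashed = [
            type(p)(mask=p.mask, score=p.score**3) for p in preds
        ]  # strictly monotone transform of scores
        assert ap_at(squashed, truths, 0.5) == pytest.approx(base, abs=1e-12)

    def test_anti_monotone_in_iou_threshold(self):
        rng = np.random.default_rng(2)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            truths = random_instances(rng, SHAPE, 4, with_scores=False)
            preds = random_instances(rng, SHAPE, 6)
            aps = [ap_at(preds, truths, t) for t in COCO_IOU_THRESHOLDS]
            for lo, hi in zip(aps, aps[1:]):
                assert lo >= hi - 1e-12


class TestMeanAP:
    def test_single_category_map_equals_ap(self):
        assert mean_average_precision([0.73]) == pytest.approx(0.73)

    def test_two_category_mean_and_permutation_symmetry(self):
        assert mean_average_precision([0.4, 0.6]) == pytest.approx(0.5)
        assert mean_average_precision([0.6, 0.4]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_average_precision([])


class TestAreaBands:
    def test_printed_band_thresholds(self):
        assert AREA_BANDS["small"] == (0.0, 1024.0)
        assert AREA_BANDS["medium"] == (1024.0, 9216.0)
        assert AREA_BANDS["large"][0] == 9216.0

    def test_31x31_truth_is_small_50x50_is_medium(self):
        small_t = square_instance(5, 5, 31)
        med_t = square_instance(40, 40, 50)
        preds = [square_instance(5, 5, 31, score=0.9), square_instance(40, 40, 50, score=0.8)]
        strata = area_stratified_ap(preds, [small_t, med_t], iou_thresholds=(0.5,))
        assert strata["small"] == pytest.approx(1.0)
        assert strata["medium"] == pytest.approx(1.0)
        assert strata["large"] is None

    def test_large_only_dataset_leaves_small_medium_undefined(self):
        truths = [square_instance(0, 0, 99)]  # 99x99 bbox > 96^2
        preds = [square_instance(0, 0, 99, score=0.9)]
        strata = area_stratified_ap(preds, truths)
        assert strata["small"] is None and strata["medium"] is None
        assert strata["large"] == pytest.approx(1.0)

    def test_out_of_band_match_is_ignored_not_penalised(self):
        truths = [square_instance(5, 5, 20), square_instance(50, 50, 60)]
        preds = [
            square_instance(50, 50, 60, score=0.95),  # matches the medium truth
            square_instance(5, 5, 20, score=0.5),
        ]
        small = ap_at(preds, truths, 0.5, area_range=AREA_BANDS["small"])
        assert small == pytest.approx(1.0)  # big pred dropped, not an FP


class TestCocoAp:
    def test_perfect_predictions_unit_everywhere(self):
        truths = [disc_instance(SHAPE, (30, 30), 10), disc_instance(SHAPE, (70, 60), 12)]
        preds = [disc_instance(SHAPE, (30, 30), 10, 0.9), disc_instance(SHAPE, (70, 60), 12, 0.8)]
        s = coco_ap(preds, truths)
        assert s.ap == pytest.approx(1.0)
        assert s.ap50 == pytest.approx(1.0)
        assert s.ap75 == pytest.approx(1.0)

    def test_iou_point6_fixture_lenient_vs_strict(self):
        # one truth square 20x20; prediction shifted to overlap with IoU = 0.6:
        # intersection 300 vs union 500 via a 20x15 offset overlap
        truth = square_instance(10, 10, 20)
        pred_mask = np.zeros(SHAPE, bool)
        pred_mask[10:30, 15:35] = True  # intersection 20x15=300, union 2*400-300=500
        from voidspot.instances import SpotInstance, iou_mask

        pred = SpotInstance(mask=pred_mask, score=0.9)
        assert iou_mask(pred.mask, truth.mask) == pytest.approx(0.6)
        s = coco_ap([pred], [truth])
        assert s.ap50 == pytest.approx(1.0)
        assert s.ap75 == pytest.approx(0.0)

    def test_ap_never_exceeds_ap50(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            truths = random_instances(rng, SHAPE, 4, with_scores=False)
            preds = random_instances(rng, SHAPE, 5)
            s = coco_ap(preds, truths)
            assert s.ap <= s.ap50 + 1e-12

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            coco_ap([disc_instance(SHAPE, (30, 30), 10, 0.9)], [])


class TestOracleAgreement:
    """Dual-route checks against the independent evaluators."""

    def test_exact_ap_matches_brute_force_step_integral(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            truths = random_instances(rng, SHAPE, int(rng.integers(1, 6)), with_scores=False)
            preds = random_instances(rng, SHAPE, int(rng.integers(0, 10)))
            got = ap_at(preds, truths, 0.5, method="exact")
            want = brute_force_ap_exact(
                [p.mask for p in preds], [p.score for p in preds], [t.mask for t in truths], 0.5
            )
            assert got == pytest.approx(want, abs=1e-9)

    def test_coco_ap_matches_reference_evaluator_on_json(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            truths_by_img = {}
            preds_by_img = {}
            truth_anns, pred_anns = [], []
            gid = pid = 1
            for img_id in (1, 2):
                truths = random_instances(rng, SHAPE, int(rng.integers(1, 5)), with_scores=False)
                preds = random_instances(rng, SHAPE, int(rng.integers(1, 8)))
                # perturbed copies of some truths so matches exist
                for k, t in enumerate(truths[: len(preds)]):
                    if rng.random() < 0.6:
                        preds[k] = type(t)(mask=t.mask, score=float(rng.uniform(0.1, 1)))
                truths_by_img[img_id] = truths
                preds_by_img[img_id] = preds
                for t in truths:
                    truth_anns.append(
                        {"id": gid, "image_id": img_id, "segmentation": rle_encode(t.mask)}
                    )
                    gid += 1
                for p in preds:
                    pred_anns.append(
                        {
                            "id": pid,
                            "image_id": img_id,
                            "segmentation": rle_encode(p.mask),
                            "score": p.score,
                        }
                    )
                    pid += 1
            truth_json = {"annotations": truth_anns}
            pred_json = {"annotations": pred_anns}
            for thr in (0.5, 0.75):
                got = ap_at_dataset(preds_by_img, truths_by_img, thr)
                want = ref_evaluate(truth_json, pred_json, thr)
                assert got == pytest.approx(want, abs=1e-6)
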