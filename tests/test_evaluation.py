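"""Evaluation protocol vs exhaustive set-operation oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pointcell as pc
from pointcell.evaluation import evaluate_scene, mask_iou

from conftest import random_mask_set


def square(size, y0, x0, h, w):
    m = np.zeros((size, size), dtype=bool)
    m[y0 : y0 + h, x0 : x0 + w] = True
    return m


# ----------------------------------------------------------------- oracles
def oracle_dsc(a, b):
    inter = sum(1 for p in zip(a.ravel(), b.ravel()) if p[0] and p[1])
    return 2 * inter / (a.sum() + b.sum()) if (a.sum() + b.sum()) else 0.0


def oracle_match(gt, pred, thr):
    """Greedy matching by explicit repeated argmax over the DSC table."""
    table = {(i, j): oracle_dsc(g, p) for i, g in enumerate(gt.masks) for j, p in enumerate(pred.masks)}
    pairs, used_g, used_p = [], set(), set()
    while True:
        best = None
        for (i, j), d in sorted(table.items()):
            if i in used_g or j in used_p or d < thr:
                continue
            if best is None or d > best[2]:
                best = (i, j, d)
        if best is None:
            break
        pairs.append(best)
        used_g.add(best[0])
        used_p.add(best[1])
    return pairs


def oracle_pixel_counts(g, p):
    tp = fn = fp = tn = 0
    for gv, pv in zip(g.ravel(), p.ravel()):
        if gv and pv:
            tp += 1
        elif gv:
            fn += 1
        elif pv:
            fp += 1
        else:
            tn += 1
    return tp, fn, fp, tn


class TestDsc:
    def test_identical_disjoint_and_half(self):
        a = square(8, 0, 0, 2, 2)
        assert pc.dsc(a, a) == 1.0
        assert pc.dsc(a, square(8, 5, 5, 2, 2)) == 0.0
        assert pc.dsc(square(8, 0, 0, 2, 2), square(8, 0, 1, 2, 2)) == 0.5  # 2*2/8

    def test_both_empty_warns_zero(self):
        z = np.zeros((4, 4), bool)
        with pytest.warns(UserWarning):
            assert pc.dsc(z, z) == 0.0


class TestMatching:
    def test_identity_prediction_fully_matched(self, rng):
        gt = random_mask_set(rng, 24, 3)
        m = pc.match_instances(gt, gt, 0.7)
        assert len(m.pairs) == len(gt)
        assert all(d == 1.0 for _, _, d in m.pairs)

    def test_one_pred_covering_two_gt_matches_once(self):
        gt = pc.InstanceMaskSet([square(16, 2, 2, 6, 6), square(16, 4, 4, 6, 6)])
        pred = pc.InstanceMaskSet([square(16, 2, 2, 6, 6)])
        m = pc.match_instances(gt, pred, 0.7)
        assert m.pairs == [(0, 0, 1.0)]
        assert m.unmatched_gt == [1]

    def test_empty_predictions_leave_all_unmatched(self, rng):
        gt = random_mask_set(rng, 24, 2)
        m = pc.match_instances(gt, pc.InstanceMaskSet([]), 0.7)
        assert m.unmatched_gt == list(range(len(gt)))
        assert pc.fnr_object(m, len(gt)) == 1.0

    def test_greedy_matches_oracle_on_random_scenes(self, rng):
        for _ in range(50):
            gt = random_mask_set(rng, 20, int(rng.integers(1, 5)))
            pred = random_mask_set(rng, 20, int(rng.integers(1, 5)))
            got = pc.match_instances(gt, pred, 0.5).pairs
            exp = oracle_match(gt, pred, 0.5)
            assert {(i, j) for i, j, _ in got} == {(i, j) for i, j, _ in exp}

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_threshold_monotonicity(self, seed):
        """Raising the threshold never decreases FNRo nor gains matches."""
        r = np.random.default_rng(seed)
        gt = random_mask_set(r, 20, int(r.integers(1, 4)))
        pred = random_mask_set(r, 20, int(r.integers(1, 4)))
        prev_matched, prev_fnro = None, None
        for thr in (0.3, 0.5, 0.7, 0.9):
            m = pc.match_instances(gt, pred, thr)
            fnro = pc.fnr_object(m, len(gt))
            if prev_matched is not None:
                assert len(m.pairs) <= prev_matched
                assert fnro >= prev_fnro
            prev_matched, prev_fnro = len(m.pairs), fnro


class TestPixelMetrics:
    def test_perfect_pair(self, rng):
        gt = random_mask_set(rng, 16, 2)
        m = pc.match_instances(gt, gt, 0.7)
        tprs, fprs = pc.pixel_metrics(m, gt, gt)
        assert tprs == [1.0, 1.0] and fprs == [0.0, 0.0]

    def test_shifted_square_counts(self):
        """10x10 image, 4x4 gt vs 1-px shift: TP 12, FN 4, FP 4, TN 80."""
        gt = pc.InstanceMaskSet([square(10, 3, 3, 4, 4)])
        pred = pc.InstanceMaskSet([square(10, 3, 4, 4, 4)])
        m = pc.match_instances(gt, pred, 0.7)  # dsc 0.75 passes
        tprs, fprs = pc.pixel_metrics(m, gt, pred)
        assert tprs[0] == pytest.approx(12 / 16)
        assert fprs[0] == pytest.approx(4 / 84)

    def test_unmatched_gt_excluded_from_aggregates(self):
        """Exclusion rule: an undetected cell changes FNRo only."""
        g1, p1 = square(20, 2, 2, 5, 5), square(20, 2, 2, 5, 5)
        lonely = square(20, 12, 12, 4, 4)
        res_without = evaluate_scene(pc.InstanceMaskSet([g1]), pc.InstanceMaskSet([p1]))
        res_with = evaluate_scene(pc.InstanceMaskSet([g1, lonely]), pc.InstanceMaskSet([p1]))
        assert res_with["tprp"] == res_without["tprp"]
        assert res_with["fprp"] == res_without["fprp"]
        assert res_with["fnro"] == 0.5 and res_without["fnro"] == 0.0

    def test_ignore_mask_pixels_dropped_from_counts(self):
        gt_m = square(10, 3, 3, 4, 4)
        pred_m = square(10, 3, 4, 4, 4)
        ignore = np.zeros((10, 10), bool)
        ignore[3, :] = True  # drop one row: TP 9, FN 3, FP 3
        gt = pc.InstanceMaskSet([gt_m], ignore_mask=ignore)
        pred = pc.InstanceMaskSet([pred_m])
        m = pc.match_instances(gt, pred, 0.5)
        tprs, fprs = pc.pixel_metrics(m, gt, pred)
        assert tprs[0] == pytest.approx(9 / 12)
        assert fprs[0] == pytest.approx(3 / (90 - 12))

    def test_matches_oracle_on_random_scenes(self, rng):
        for _ in range(100):
            gt = random_mask_set(rng, 20, int(rng.integers(1, 5)))
            pred = random_mask_set(rng, 20, int(rng.integers(1, 5)))
            m = pc.match_instances(gt, pred, 0.6)
            tprs, fprs = pc.pixel_metrics(m, gt, pred)
            for (i, j, d), tpr, fpr in zip(m.pairs, tprs, fprs):
                tp, fn, fp, tn = oracle_pixel_counts(gt.masks[i], pred.masks[j])
                assert d == pytest.approx(oracle_dsc(gt.masks[i], pred.masks[j]))
                assert tpr == pytest.approx(tp / (tp + fn))
                assert fpr == pytest.approx(fp / (fp + tn))


class TestFnro:
    def test_ratios(self):
        m = pc.MatchResult(pairs=[(0, 0, 1.0)] * 0, unmatched_gt=[0], unmatched_pred=[], threshold=0.7)
        assert pc.fnr_object(pc.MatchResult([], [0], [], 0.7), 4) == 0.25
        assert pc.fnr_object(pc.MatchResult([], [], [], 0.7), 3) == 0.0
        with pytest.raises(ValueError):
            pc.fnr_object(m, 0)


class TestCocoAp:
    def test_perfect_predictions_give_unit_ap(self, rng):
        gts = [random_mask_set(rng, 20, 3) for _ in range(3)]
        scores = [np.ones(3)] * 3
        ap, ap50, ap75 = pc.coco_ap(gts, gts, scores)
        assert ap == ap50 == ap75 == 1.0

    def test_no_predictions_zero_ap(self, rng):
        gts = [random_mask_set(rng, 20, 2)]
        ap, ap50, _ = pc.coco_ap(gts, [pc.InstanceMaskSet([])], [np.zeros(0)])
        assert ap == 0.0 and ap50 == 0.0

    def test_one_of_two_detected_half_ap50(self):
        gt = pc.InstanceMaskSet([square(16, 1, 1, 5, 5), square(16, 9, 9, 5, 5)])
        pred = pc.InstanceMaskSet([square(16, 1, 1, 5, 5)])
        _, ap50, _ = pc.coco_ap([gt], [pred], [np.ones(1)])
        # hand-walked PR curve: precision 1 up to recall 0.5, then 0
        assert ap50 == pytest.approx(51 / 101)

    def test_missing_scores_rejected(self, rng):
        gt = random_mask_set(rng, 16, 2)
        with pytest.raises(ValueError):
            pc.coco_ap([gt], [gt], [np.ones(1)])


class TestInvariance:
    def test_metrics_invariant_under_joint_flip(self, rng):
        gt = random_mask_set(rng, 24, 3)
        pred = random_mask_set(rng, 24, 3)
        rep1 = pc.evaluate_dataset([gt], [pred], [np.ones(3)])
        fgt = pc.InstanceMaskSet([np.fliplr(np.rot90(m)) for m in gt.masks])
        fpred = pc.InstanceMaskSet([np.fliplr(np.rot90(m)) for m in pred.masks])
        rep2 = pc.evaluate_dataset([fgt], [fpred], [np.ones(3)])
        for f in ("dsc_mean", "tprp_mean", "fprp_mean", "fnro_mean", "ap"):
            assert getattr(rep1, f) == pytest.approx(getattr(rep2, f), nan_ok=True)


class TestStratifiedReport:
    def test_single_stratum_equals_global(self, rng):
        gts = [random_mask_set(rng, 24, 3) for _ in range(4)]
        metas = [{"n_cells": 3, "achieved_overlap_rate": 0.05}] * 4
        rep = pc.stratified_report(gts, gts, metas, [np.ones(3)] * 4)
        assert set(rep.strata) == {(3, 0)}
        assert rep.strata[(3, 0)]["dsc_mean"] == rep.dsc_mean

    def test_empty_strata_absent_and_unknown_bucketed(self, rng):
        gts = [random_mask_set(rng, 24, 2) for _ in range(2)]
        metas = [{"n_cells": 2, "achieved_overlap_rate": 0.45}, {}]
        with pytest.warns(UserWarning, match="metadata"):
            rep = pc.stratified_report(gts, gts, metas)
        assert (2, 4) in rep.strata and (-1, -1) in rep.strata
        assert len(rep.strata) == 2

    def test_per_stratum_matches_independent_recomputation(self, rng):
        gts = [random_mask_set(rng, 24, 2), random_mask_set(rng, 24, 4)]
        preds = [random_mask_set(rng, 24, 2), random_mask_set(rng, 24, 4)]
        metas = [
            {"n_cells": 2, "achieved_overlap_rate": 0.05},
            {"n_cells": 4, "achieved_overlap_rate": 0.35},
        ]
        rep = pc.stratified_report(gts, preds, metas)
        for k, idx in (((2, 0), 0), ((4, 3), 1)):
            solo = pc.evaluate_dataset([gts[idx]], [preds[idx]])
            assert rep.strata[k]["dsc_mean"] == pytest.approx(solo.dsc_mean, nan_ok=True)


def test_mask_iou_basics():
    a = square(8, 0, 0, 4, 4)
    b = square(8, 0, 2, 4, 4)
    assert mask_iou(a, a) == 1.0
    assert mask_iou(a, b) == pytest.approx(8 / 24)
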