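"""Detection matching, AP, Dice, ECE, S-measure and weighted F-measure."""

import itertools
import math

import numpy as np
import pytest

from greenprompt.boxes import Box
from greenprompt.metrics import (
    COCO_THRESHOLDS,
    average_precision,
    dice,
    ece,
    mask_iou,
    match,
    precision_recall,
    recall_at_maxdet,
    s_measure,
    size_stratified_ap,
    weighted_fmeasure,
)


def B(x, y, w, h, score=1.0, id=-1):
    return Box(x, y, x + w, y + h, score, id)


class TestMatch:
    def test_exact_prediction(self):
        gt = [B(0, 0, 10, 10)]
        for t in (0.5, 0.75, 0.95):
            table = match([B(0, 0, 10, 10, 0.9)], gt, t)
            assert (table.tp, table.fp, table.fn) == (1, 0, 0)

    def test_below_threshold_is_fp_and_fn(self):
        table = match([B(0, 0, 10, 4, 0.9)], [B(0, 0, 10, 10)], 0.5)
        assert (table.tp, table.fp, table.fn) == (0, 1, 1)

    def test_greedy_matches_equal_enumeration_oracle(self):
        # 3 predictions / 2 GT: compare against explicit enumeration of
        # assignments under the greedy score-descending rule
        preds = [B(0, 0, 10, 10, 0.9, 0), B(1, 0, 10, 10, 0.8, 1),
                 B(20, 0, 8, 8, 0.7, 2)]
        gts = [B(0, 0, 10, 10), B(19, 0, 9, 9)]
        table = match(preds, gts, 0.5)
        # oracle: process by descending score, each takes best free GT
        from greenprompt.boxes import iou as boxiou

        free = set(range(len(gts)))
        expected = {}
        for pi in sorted(range(3), key=lambda i: -preds[i].score):
            cands = [(boxiou(preds[pi], gts[j]), j) for j in free]
            cands = [(v, j) for v, j in cands if v >= 0.5]
            if cands:
                v, j = max(cands)
                expected[pi] = j
                free.discard(j)
        got = {int(o): int(m) for o, m in zip(
            np.argsort([-p.score for p in preds], kind="stable"),
            table.pred_match) if m >= 0}
        assert got == expected
        assert table.tp == len(expected)

    def test_invariants_hold(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            preds = [B(*rng.uniform(0, 30, 2), *rng.uniform(2, 20, 2),
                       rng.uniform(0, 1), k) for k in range(6)]
            gts = [B(*rng.uniform(0, 30, 2), *rng.uniform(2, 20, 2))
                   for _ in range(4)]
            t = match(preds, gts, 0.5)
            assert t.tp + t.fn == len(gts)
            assert t.tp + t.fp == len(preds)


class TestPrecisionRecall:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [(5, 0, 0, (1.0, 1.0)), (0, 3, 2, (0.0, 0.0)), (3, 1, 2, (0.75, 0.6))],
    )
    def test_arithmetic(self, tp, fp, fn, expected):
        class T:
            pass

        t = T()
        t.tp, t.fp, t.fn = tp, fp, fn
        assert precision_recall(t) == pytest.approx(expected)


def _naive_ap_101(scored_flags, n_gt):
    """Independent 101-point AP: explicit precision envelope on the grid."""
    flags = [f for _, f in sorted(scored_flags, key=lambda t: -t[0])]
    points = []
    tp = fp = 0
    for f in flags:
        tp, fp = tp + f, fp + (not f)
        points.append((tp / n_gt, tp / (tp + fp)))
    total = 0.0
    for r in np.linspace(0, 1, 101):
        best = 0.0
        for rec, prec in points:
            if rec >= r - 1e-12:
                best = max(best, prec)
        total += best
    return total / 101.0


class TestAveragePrecision:
    def test_single_correct_detection(self):
        gt = [B(0, 0, 10, 10)]
        ap = average_precision([B(0, 0, 10, 10, 0.9)], gt, thresholds=[0.5])
        assert ap[0.5] == pytest.approx(1.0)

    def test_fp_above_tp(self):
        gt = [B(0, 0, 10, 10)]
        preds = [B(40, 40, 5, 5, 0.9, 0), B(0, 0, 10, 10, 0.5, 1)]
        ap = average_precision(preds, gt, thresholds=[0.5])
        assert ap[0.5] == pytest.approx(
            _naive_ap_101([(0.9, False), (0.5, True)], 1)
        )

    def test_perfect_predictions_at_all_thresholds(self):
        rng = np.random.default_rng(1)
        gts = [B(k * 20, 0, 10, 10) for k in range(4)]
        preds = [B(k * 20, 0, 10, 10, float(rng.uniform(0.1, 1)), k)
                 for k in range(4)]
        ap = average_precision(preds, gts)
        assert all(v == pytest.approx(1.0) for v in ap.values())

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n_gt = int(rng.integers(1, 5))
            gts = [B(k * 25, 0, 12, 12) for k in range(n_gt)]
            preds = []
            for k in range(int(rng.integers(1, 10))):
                if rng.random() < 0.5 and n_gt:
                    j = int(rng.integers(0, n_gt))
                    preds.append(B(j * 25 + rng.uniform(-1, 1), 0, 12, 12,
                                   float(rng.uniform(0, 1)), k))
                else:
                    preds.append(B(500 + k * 30, 0, 10, 10,
                                   float(rng.uniform(0, 1)), k))
            ap = average_precision(preds, gts, thresholds=[0.5])
            table = match(preds, gts, 0.5)
            flags = list(zip(table.pred_scores, table.pred_match >= 0))
            assert ap[0.5] == pytest.approx(_naive_ap_101(flags, n_gt))

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(3)
        gts = [B(k * 25, 0, 12, 12) for k in range(3)]
        preds = [B(k * 25 + rng.uniform(-3, 3), 0, 12, 12,
                   float(rng.uniform(0.1, 0.9)), k) for k in range(6)]
        ap1 = average_precision(preds, gts)
        squashed = [p.with_score(p.score**3) for p in preds]
        ap2 = average_precision(squashed, gts)
        assert list(ap1.values()) == pytest.approx(list(ap2.values()))

    def test_no_gt_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            ap = average_precision([B(0, 0, 5, 5, 0.5)], [], thresholds=[0.5])
        assert math.isnan(ap[0.5])


class TestSizeStrata:
    def test_all_small(self):
        gts = [B(k * 30, 0, 12, 16) for k in range(3)]  # diagonal 20
        preds = [B(k * 30, 0, 12, 16, 0.9, k) for k in range(3)]
        out = size_stratified_ap([(preds, gts)])
        assert out["small"] == pytest.approx(1.0)
        assert math.isnan(out["medium"]) and math.isnan(out["large"])

    def test_boundary_diagonal_exactly_32_is_medium(self):
        from greenprompt.metrics import _diagonal_stratum

        assert _diagonal_stratum(B(0, 0, 19.2, 25.6)) == "medium"  # d = 32
        assert _diagonal_stratum(B(0, 0, 19.2, 25.5)) == "small"
        assert _diagonal_stratum(B(0, 0, 57.6, 76.8)) == "large"  # d = 96

    def test_stratum_equals_subset_recomputation(self, battery10):
        from greenprompt import ProposalConfig, generate_proposals, vc_nms
        from greenprompt.metrics import ap_over_range, _diagonal_stratum

        pairs = []
        for sc in battery10[:4]:
            kept = vc_nms(sc.image, generate_proposals(
                sc, ProposalConfig(seed=sc.provenance.seed))).kept
            pairs.append((kept, sc.gt_boxes))
        strata = size_stratified_ap(pairs)
        for name in ("small", "medium"):
            subset = [
                ([p for p in preds if _diagonal_stratum(p) == name],
                 [g for g in gts if _diagonal_stratum(g) == name])
                for preds, gts in pairs
            ]
            if all(not g for _, g in subset):
                continue
            aps = ap_over_range(subset)
            assert strata[name] == pytest.approx(float(np.mean(list(aps.values()))))


class TestRecallAtMaxDet:
    def test_monotone_in_maxdet(self):
        rng = np.random.default_rng(4)
        gts = [B(k * 25, 0, 12, 12) for k in range(8)]
        preds = [B(k * 25 + rng.uniform(-2, 2), 0, 12, 12,
                   float(rng.uniform(0, 1)), k) for k in range(8)]
        pairs = [(preds, gts)]
        assert recall_at_maxdet(pairs, 100) >= recall_at_maxdet(pairs, 10)
        assert recall_at_maxdet(pairs, 10) >= recall_at_maxdet(pairs, 2)


class TestDice:
    def test_extremes(self):
        a = np.zeros((6, 6), bool)
        a[:3] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        assert dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_identity_with_iou(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a = rng.random((12, 12)) < rng.uniform(0.1, 0.9)
            b = rng.random((12, 12)) < rng.uniform(0.1, 0.9)
            i = mask_iou(a, b)
            d = dice(a, b)
            assert abs(d - 2 * i / (1 + i)) < 1e-12
            assert d >= i - 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestEce:
    def test_confident_and_correct_is_zero(self):
        gt = np.array([[True, False], [False, True]])
        p = gt.astype(float)
        assert ece(p, gt) == 0.0

    def test_confident_and_wrong_is_one(self):
        gt = np.zeros((4, 4), bool)
        p = np.ones((4, 4))
        assert ece(p, gt) == pytest.approx(1.0)

    def test_hand_built_two_bin_case(self):
        # 4 px at conf 0.6 (pred 1), half correct; 4 px at conf 0.92
        # (pred 0), all correct:
        # ECE = 0.5*|0.5-0.6| + 0.5*|1.0-0.92| = 0.09
        p = np.array([0.6, 0.6, 0.6, 0.6, 0.08, 0.08, 0.08, 0.08])
        gt = np.array([1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        assert ece(p, gt) == pytest.approx(0.5 * 0.1 + 0.5 * 0.08)

    def test_perfectly_calibrated_bins(self):
        # conf 0.75 pixels correct exactly 75% of the time -> ECE = 0
        p = np.full(100, 0.75)
        gt = np.zeros(100, bool)
        gt[:75] = True
        assert ece(p, gt) == pytest.approx(0.0)


def _naive_s_measure(pred, gt, alpha=0.5):
    """Loop-based independent reimplementation of the structure measure."""
    pred = pred.astype(float)
    gt = gt.astype(bool)
    u = gt.mean()
    if u == 0:
        return 1 - pred.mean()
    if u == 1:
        return pred.mean()

    def obj(x_vals):
        if x_vals.size == 0:
            return 0.0
        x = x_vals.mean()
        sx = x_vals.std(ddof=1) if x_vals.size > 1 else 0.0
        return 2 * x / (x * x + 1 + sx + np.finfo(float).eps)

    fg = np.where(gt, pred, 0)
    bg = np.where(~gt, 1 - pred, 0)
    s_o = u * obj(fg[gt]) + (1 - u) * obj(bg[~gt])
    ys, xs = np.nonzero(gt)
    cy, cx = int(round(ys.mean())), int(round(xs.mean()))
    h, w = gt.shape
    total = 0.0
    for rows, cols in itertools.product(
        [(0, cy + 1), (cy + 1, h)], [(0, cx + 1), (cx + 1, w)]
    ):
        gq = gt[rows[0]:rows[1], cols[0]:cols[1]].astype(float)
        pq = pred[rows[0]:rows[1], cols[0]:cols[1]]
        wq = gq.size / gt.size
        n = gq.size
        if n == 0:
            total += wq
            continue
        x, y = pq.mean(), gq.mean()
        if n > 1:
            sx = ((pq - x) ** 2).sum() / (n - 1)
            sy = ((gq - y) ** 2).sum() / (n - 1)
            sxy = ((pq - x) * (gq - y)).sum() / (n - 1)
        else:
            sx = sy = sxy = 0.0
        a = 4 * x * y * sxy
        b = (x * x + y * y) * (sx + sy)
        if a != 0:
            q = a / (b + np.finfo(float).eps)
        else:
            q = 1.0 if b == 0 else 0.0
        total += wq * q
    return max(alpha * s_o + (1 - alpha) * total, 0.0)


class TestStructureMeasure:
    def test_perfect_prediction(self):
        gt = np.zeros((20, 20), bool)
        gt[5:15, 5:15] = True
        assert s_measure(gt.astype(float), gt) == pytest.approx(1.0, abs=1e-6)

    def test_checkerboard_vs_half_plane_matches_oracle(self):
        gt = np.zeros((16, 16), bool)
        gt[:8] = True
        pred = np.indices((16, 16)).sum(axis=0) % 2 * 1.0
        assert s_measure(pred, gt) == pytest.approx(_naive_s_measure(pred, gt))

    def test_random_maps_match_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            gt = rng.random((14, 14)) < 0.4
            if not gt.any() or gt.all():
                continue
            pred = rng.random((14, 14))
            assert s_measure(pred, gt) == pytest.approx(_naive_s_measure(pred, gt))

    def test_empty_and_full_gt_fallbacks(self):
        pred = np.full((5, 5), 0.2)
        assert s_measure(pred, np.zeros((5, 5), bool)) == pytest.approx(0.8)
        assert s_measure(pred, np.ones((5, 5), bool)) == pytest.approx(0.2)


class TestWeightedFMeasure:
    def test_perfect_prediction(self):
        gt = np.zeros((20, 20), bool)
        gt[6:14, 6:14] = True
        assert weighted_fmeasure(gt.astype(float), gt) == pytest.approx(1.0)

    def test_inverted_prediction_is_zero(self):
        gt = np.zeros((20, 20), bool)
        gt[6:14, 6:14] = True  # margin > blur radius from the border
        assert weighted_fmeasure(1.0 - gt, gt) == pytest.approx(0.0, abs=1e-9)

    def test_bounded_and_monotone_in_quality(self):
        gt = np.zeros((24, 24), bool)
        gt[6:18, 6:18] = True
        good = gt.astype(float)
        worse = gt.astype(float) * 0.6
        assert 0.0 <= weighted_fmeasure(worse, gt) < weighted_fmeasure(good, gt) <= 1.0

    def test_empty_gt_warns(self):
        with pytest.warns(UserWarning):
            assert weighted_fmeasure(np.ones((5, 5)) * 0.3,
                                     np.zeros((5, 5), bool)) == 0.0
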