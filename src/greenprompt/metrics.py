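"""Detection and segmentation evaluation metrics.

Detection side: greedy score-ranked one-to-one matching, precision/recall,
COCO-style 101-point interpolated average precision over IoU thresholds
0.5:0.95, size-stratified AP (strata by ground-truth box diagonal), and
averaged recall at bounded detection counts.

Mask side: Dice, expected calibration error (ECE) over pixel-pooled
confidences, the structure measure S_m (object- plus region-aware
structural similarity), and the weighted F-measure with
distance-weighted errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .boxes import Box, iou as box_iou

__all__ = [
    "MatchTable",
    "EvalReport",
    "mask_iou",
    "match",
    "precision_recall",
    "average_precision",
    "ap_over_range",
    "size_stratified_ap",
    "recall_at_maxdet",
    "dice",
    "ece",
    "s_measure",
    "weighted_fmeasure",
    "evaluate_detections",
    "COCO_THRESHOLDS",
]

COCO_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))

Instance = Box | np.ndarray  # a detection is a box or a binary mask


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter / union) if union else 0.0


def _pair_iou(pred, gt, iou_kind: Literal["box", "mask"]) -> float:
    return box_iou(pred, gt) if iou_kind == "box" else mask_iou(pred, gt)


@dataclass
class MatchTable:
    """One-to-one greedy matching at a fixed IoU threshold.

    ``pred_match[i]`` is the matched GT index (or -1), ``pred_iou[i]`` the
    IoU of that match; invariants TP + FN = #GT and TP + FP = #predictions
    (after the max_det cut) hold by construction.
    """

    pred_match: np.ndarray
    pred_iou: np.ndarray
    pred_scores: np.ndarray
    gt_matched: np.ndarray
    iou_threshold: float

    @property
    def tp(self) -> int:
        return int((self.pred_match >= 0).sum())

    @property
    def fp(self) -> int:
        return int((self.pred_match < 0).sum())

    @property
    def fn(self) -> int:
        return int((~self.gt_matched).sum())


def _scores_of(preds: Sequence, scores: Sequence[float] | None) -> np.ndarray:
    if scores is not None:
        return np.asarray(scores, dtype=np.float64)
    return np.array([p.score for p in preds], dtype=np.float64)


def match(
    predictions: Sequence,
    ground_truth: Sequence,
    iou_threshold: float = 0.5,
    iou_kind: Literal["box", "mask"] = "box",
    max_det: int | None = None,
    scores: Sequence[float] | None = None,
) -> MatchTable:
    """Score-descending greedy matching against the best unmatched GT.

    Each prediction (highest score first; ties by input order) claims the
    unmatched ground-truth instance of maximal IoU, provided that IoU meets
    the threshold.  For mask metrics pass ``iou_kind="mask"`` and supply
    ``scores`` alongside the mask arrays.
    """
    s = _scores_of(predictions, scores)
    order = np.argsort(-s, kind="stable")
    if max_det is not None:
        order = order[:max_det]
    pred_match = np.full(len(order), -1, dtype=np.int64)
    pred_iou = np.zeros(len(order), dtype=np.float64)
    gt_matched = np.zeros(len(ground_truth), dtype=bool)
    for rank, pi in enumerate(order):
        best_j, best_v = -1, 0.0
        for j, gt in enumerate(ground_truth):
            if gt_matched[j]:
                continue
            v = _pair_iou(predictions[pi], gt, iou_kind)
            if v > best_v:
                best_j, best_v = j, v
        if best_j >= 0 and best_v >= iou_threshold:
            pred_match[rank] = best_j
            pred_iou[rank] = best_v
            gt_matched[best_j] = True
    return MatchTable(
        pred_match=pred_match,
        pred_iou=pred_iou,
        pred_scores=s[order],
        gt_matched=gt_matched,
        iou_threshold=iou_threshold,
    )


def precision_recall(table: MatchTable) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); 0 when the denominator is 0."""
    tp, fp, fn = table.tp, table.fp, table.fn
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


# ---------------------------------------------------------------------------
# Average precision.
# ---------------------------------------------------------------------------

_RECALL_GRID = np.linspace(0.0, 1.0, 101)


def _pooled_tp_flags(
    image_pairs: Sequence[tuple[Sequence, Sequence]],
    iou_threshold: float,
    iou_kind: Literal["box", "mask"],
    max_det: int | None,
    scores_per_image: Sequence[Sequence[float]] | None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Match per image, then pool (score, is-TP) flags across images."""
    all_scores, all_flags, n_gt = [], [], 0
    for k, (preds, gts) in enumerate(image_pairs):
        sc = scores_per_image[k] if scores_per_image is not None else None
        t = match(preds, gts, iou_threshold, iou_kind, max_det, scores=sc)
        all_scores.append(t.pred_scores)
        all_flags.append(t.pred_match >= 0)
        n_gt += len(gts)
    scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
    flags = np.concatenate(all_flags) if all_flags else np.zeros(0, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    return scores[order], flags[order], n_gt


def _ap_from_flags(flags: np.ndarray, n_gt: int,
                   interpolation: Literal["101point", "all"] = "101point") -> float:
    if n_gt == 0:
        warnings.warn("AP undefined with no ground truth; returning NaN")
        return float("nan")
    if len(flags) == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    if interpolation == "101point":
        # precision envelope sampled on the 101-point recall grid
        prec_env = np.maximum.accumulate(precision[::-1])[::-1]
        idx = np.searchsorted(recall, _RECALL_GRID, side="left")
        sampled = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
        return float(sampled.mean())
    # all-point: exact area under the step-wise interpolated P-R curve
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    area = 0.0
    for r, p in zip(recall, prec_env):
        area += (r - r_prev) * p
        r_prev = r
    return float(area)


def average_precision(
    predictions: Sequence,
    ground_truth: Sequence,
    thresholds: Sequence[float] = COCO_THRESHOLDS,
    iou_kind: Literal["box", "mask"] = "box",
    max_det: int | None = None,
    interpolation: Literal["101point", "all"] = "101point",
    scores: Sequence[float] | None = None,
) -> dict[float, float]:
    """AP at each IoU threshold for a single image (or pooled set).

    Accepts either one image's (predictions, ground_truth) or lists of
    per-image pairs via :func:`ap_over_range` for multi-image pooling.
    """
    return ap_over_range(
        [(predictions, ground_truth)],
        thresholds,
        iou_kind=iou_kind,
        max_det=max_det,
        interpolation=interpolation,
        scores_per_image=None if scores is None else [scores],
    )


def ap_over_range(
    image_pairs: Sequence[tuple[Sequence, Sequence]],
    thresholds: Sequence[float] = COCO_THRESHOLDS,
    iou_kind: Literal["box", "mask"] = "box",
    max_det: int | None = None,
    interpolation: Literal["101point", "all"] = "101point",
    scores_per_image: Sequence[Sequence[float]] | None = None,
) -> dict[float, float]:
    """Pooled multi-image AP at each threshold (COCO-style)."""
    out = {}
    for t in thresholds:
        _, flags, n_gt = _pooled_tp_flags(
            image_pairs, t, iou_kind, max_det, scores_per_image
        )
        out[float(t)] = _ap_from_flags(flags, n_gt, interpolation)
    return out


def _diagonal_stratum(b: Box) -> str:
    # small: diagonal < 32 px; medium: 32 <= d < 96; large: d >= 96.
    d = b.diagonal
    if d < 32.0:
        return "small"
    if d < 96.0:
        return "medium"
    return "large"


def size_stratified_ap(
    image_pairs: Sequence[tuple[Sequence[Box], Sequence[Box]]],
    thresholds: Sequence[float] = COCO_THRESHOLDS,
) -> dict[str, float]:
    """Mean AP over the threshold range per GT-diagonal stratum.

    Each stratum keeps only its ground-truth boxes and the predictions
    whose own diagonal falls in the stratum; an empty stratum yields NaN.
    """
    out = {}
    for name in ("small", "medium", "large"):
        pairs = [
            (
                [p for p in preds if _diagonal_stratum(p) == name],
                [g for g in gts if _diagonal_stratum(g) == name],
            )
            for preds, gts in image_pairs
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aps = ap_over_range(pairs, thresholds)
        vals = list(aps.values())
        out[name] = float(np.mean(vals)) if not any(map(math.isnan, vals)) else float("nan")
    return out


def recall_at_maxdet(
    image_pairs: Sequence[tuple[Sequence, Sequence]],
    max_det: int,
    thresholds: Sequence[float] = COCO_THRESHOLDS,
    iou_kind: Literal["box", "mask"] = "box",
) -> float:
    """COCO-style averaged recall: mean over IoU thresholds of pooled
    recall with at most ``max_det`` highest-scored detections per image."""
    recalls = []
    for t in thresholds:
        tp = n_gt = 0
        for preds, gts in image_pairs:
            table = match(preds, gts, t, iou_kind, max_det)
            tp += table.tp
            n_gt += len(gts)
        recalls.append(tp / n_gt if n_gt else 0.0)
    return float(np.mean(recalls))


# ---------------------------------------------------------------------------
# Mask-quality metrics.
# ---------------------------------------------------------------------------


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / total


def ece(prob_map: np.ndarray, gt_mask: np.ndarray, n_bins: int = 10) -> float:
    """Expected calibration error over pixel-pooled binary confidences.

    Predicted class is ``p >= 0.5`` with confidence ``max(p, 1-p)``;
    confidences are pooled into ``n_bins`` equal-width bins over [0.5, 1]
    and ECE is the bin-weighted mean |accuracy - mean confidence| gap.
    """
    p = np.asarray(prob_map, dtype=np.float64).ravel()
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probability map outside [0, 1]")
    y = np.asarray(gt_mask, dtype=bool).ravel()
    if p.shape != y.shape:
        raise ValueError("probability map and mask shapes differ")
    pred = p >= 0.5
    conf = np.where(pred, p, 1.0 - p)
    correct = pred == y
    edges = np.linspace(0.5, 1.0, n_bins + 1)
    total = len(p)
    out = 0.0
    for m in range(n_bins):
        lo, hi = edges[m], edges[m + 1]
        sel = (conf >= lo) & (conf < hi) if m < n_bins - 1 else (conf >= lo) & (conf <= hi)
        if not sel.any():
            continue
        acc = float(correct[sel].mean())
        avg_conf = float(conf[sel].mean())
        out += sel.sum() / total * abs(acc - avg_conf)
    return float(out)


# -- structure measure (object- and region-aware structural similarity) -----


def _s_object_part(pred: np.ndarray, region: np.ndarray) -> float:
    vals = pred[region]
    if vals.size == 0:
        return 0.0
    x = float(vals.mean())
    sigma_x = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return 2.0 * x / (x * x + 1.0 + sigma_x + np.finfo(float).eps)


def _s_object(pred: np.ndarray, gt: np.ndarray) -> float:
    fg = np.where(gt, pred, 0.0)
    bg = np.where(~gt, 1.0 - pred, 0.0)
    u = float(gt.mean())
    return u * _s_object_part(fg, gt) + (1.0 - u) * _s_object_part(bg, ~gt)


def _centroid(gt: np.ndarray) -> tuple[int, int]:
    h, w = gt.shape
    if not gt.any():
        return h // 2, w // 2
    ys, xs = np.nonzero(gt)
    return int(round(float(ys.mean()))), int(round(float(xs.mean())))


def _divide(arr: np.ndarray, cy: int, cx: int):
    return (arr[:cy + 1, :cx + 1], arr[:cy + 1, cx + 1:],
            arr[cy + 1:, :cx + 1], arr[cy + 1:, cx + 1:])


def _region_ssim(pred: np.ndarray, gt: np.ndarray) -> float:
    n = pred.size
    if n == 0:
        return 1.0
    x, y = float(pred.mean()), float(gt.mean())
    if n > 1:
        sx = float(((pred - x) ** 2).sum() / (n - 1))
        sy = float(((gt - y) ** 2).sum() / (n - 1))
        sxy = float(((pred - x) * (gt - y)).sum() / (n - 1))
    else:
        sx = sy = sxy = 0.0
    alpha = 4.0 * x * y * sxy
    beta = (x * x + y * y) * (sx + sy)
    if alpha != 0.0:
        return alpha / (beta + np.finfo(float).eps)
    return 1.0 if beta == 0.0 else 0.0


def _s_region(pred: np.ndarray, gt: np.ndarray) -> float:
    cy, cx = _centroid(gt)
    h, w = gt.shape
    gq = _divide(gt.astype(np.float64), cy, cx)
    pq = _divide(pred, cy, cx)
    weights = [q.size / (h * w) for q in gq]
    return float(sum(w_ * _region_ssim(p_, g_) for w_, p_, g_ in zip(weights, pq, gq)))


def s_measure(pred_map: np.ndarray, gt_mask: np.ndarray, alpha: float = 0.5) -> float:
    """Structure measure: alpha * S_object + (1-alpha) * S_region.

    Degenerate ground truths follow the original definition: an all-empty
    GT scores ``1 - mean(pred)``, an all-full GT scores ``mean(pred)``.
    """
    pred = np.asarray(pred_map, dtype=np.float64)
    gt = np.asarray(gt_mask, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("prediction and mask shapes differ")
    u = float(gt.mean())
    if u == 0.0:
        return 1.0 - float(pred.mean())
    if u == 1.0:
        return float(pred.mean())
    q = alpha * _s_object(pred, gt) + (1.0 - alpha) * _s_region(pred, gt)
    return max(float(q), 0.0)


def weighted_fmeasure(pred_map: np.ndarray, gt_mask: np.ndarray,
                      beta2: float = 1.0) -> float:
    """Weighted F-measure with distance-based error weighting.

    Errors in the background are propagated from the nearest foreground
    pixel, smoothed with a 7x7 Gaussian (sigma 5), and down-weighted with
    distance from the object; weighted precision/recall combine with
    weight ``beta2``.  An empty ground truth yields 0 with a warning.
    """
    pred = np.asarray(pred_map, dtype=np.float64)
    gt = np.asarray(gt_mask, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("prediction and mask shapes differ")
    if not gt.any():
        warnings.warn("weighted F-measure undefined for empty ground truth; 0")
        return 0.0
    eps = np.finfo(float).eps
    err = np.abs(pred - gt.astype(np.float64))
    dst, idx = distance_transform_edt(~gt, return_indices=True)
    err_t = err.copy()
    err_t[~gt] = err[idx[0][~gt], idx[1][~gt]]
    ea = gaussian_filter(err_t, sigma=5.0, truncate=0.6, mode="constant")
    min_e_ea = err.copy()
    use_ea = gt & (ea < err)
    min_e_ea[use_ea] = ea[use_ea]
    b = np.ones_like(err)
    b[~gt] = 2.0 - np.exp(np.log(0.5) / 5.0 * dst[~gt])
    ew = min_e_ea * b
    tpw = float(gt.sum()) - float(ew[gt].sum())
    fpw = float(ew[~gt].sum())
    recall_w = 1.0 - float(ew[gt].mean())
    precision_w = tpw / (eps + tpw + fpw)
    return float(
        (1.0 + beta2) * precision_w * recall_w / (eps + beta2 * precision_w + recall_w)
    )


# ---------------------------------------------------------------------------
# Bundled report.
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Bundle of the detection/segmentation metric suite for one run."""

    precision: float = 0.0
    recall: float = 0.0
    ap_at: dict[float, float] = field(default_factory=dict)
    ap_range: float = float("nan")
    ap_small: float = float("nan")
    ap_medium: float = float("nan")
    ap_large: float = float("nan")
    recall_at_maxdet: dict[int, float] = field(default_factory=dict)
    iou_mean: float = float("nan")
    dice_mean: float = float("nan")
    ece: float = float("nan")
    sm: float = float("nan")
    wfm: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "ap_at": {str(k): v for k, v in self.ap_at.items()},
            "ap_range": self.ap_range,
            "ap_small": self.ap_small,
            "ap_medium": self.ap_medium,
            "ap_large": self.ap_large,
            "recall_at_maxdet": {str(k): v for k, v in self.recall_at_maxdet.items()},
            "iou_mean": self.iou_mean,
            "dice_mean": self.dice_mean,
            "ece": self.ece,
            "sm": self.sm,
            "wfm": self.wfm,
        }


def evaluate_detections(
    image_pairs: Sequence[tuple[Sequence[Box], Sequence[Box]]],
    report_thresholds: Sequence[float] = (0.5, 0.75, 0.9),
) -> EvalReport:
    """Detection-side EvalReport over a set of images (box IoU matching)."""
    ap = ap_over_range(image_pairs, COCO_THRESHOLDS)
    tp = fp = fn = 0
    ious = []
    for preds, gts in image_pairs:
        t = match(preds, gts, 0.5)
        tp, fp, fn = tp + t.tp, fp + t.fp, fn + t.fn
        ious.extend(t.pred_iou[t.pred_match >= 0].tolist())
    strata = size_stratified_ap(image_pairs)
    return EvalReport(
        precision=tp / (tp + fp) if tp + fp else 0.0,
        recall=tp / (tp + fn) if tp + fn else 0.0,
        ap_at={t: ap[t] for t in report_thresholds if t in ap},
        ap_range=float(np.mean(list(ap.values()))),
        ap_small=strata["small"],
        ap_medium=strata["medium"],
        ap_large=strata["large"],
        recall_at_maxdet={
            10: recall_at_maxdet(image_pairs, 10),
            100: recall_at_maxdet(image_pairs, 100),
        },
        iou_mean=float(np.mean(ious)) if ious else float("nan"),
    )
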