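"""Vegetation-Cover-Aware NMS and reference NMS baselines.

Open-set detectors prompted with a generic phrase ("single vegetable") emit
dense redundant proposals around plants: stacks of nested near-duplicates on
one plant, and oversized union boxes that swallow several neighbouring
plants and — because detector confidence tends to grow with box area —
often outscore the tight per-plant boxes.  Confidence-plus-IoU suppression
(greedy NMS, Soft-NMS) then keeps the wrong boxes.

VC-NMS re-scores and suppresses in two stages:

stage 1 (re-scoring)
    Each box's working score becomes the composite
    ``beta * NCGI + (1 - beta) * score``; then any box that highly overlaps
    (RIoU >= N_t) a later-ordered box while having at least as many
    overlapping neighbours is attenuated once by ``1 - oven / max_oven``.
    Union boxes covering several plants have both top NCGI and top overlap
    count, so the attenuation cancels exactly the boxes the composite score
    would otherwise favour.

stage 2 (suppression)
    Soft-NMS-style iterative selection, but the Gaussian decay
    ``exp(-RIoU^2 / sigma)`` is driven by the *Relative* IoU, so nested
    duplicates (RIoU = 1 regardless of area ratio) are decisively decayed
    while adjacent plants (low RIoU) are untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .boxes import Box, OverlapGraph, build_overlap_graph, iou, riou
from .vegindex import RgbImage, VegetationMask, ncgi_normalized, vegetation_mask

__all__ = [
    "VcnmsConfig",
    "ScoredCandidateSet",
    "SuppressedBox",
    "NmsResult",
    "composite_score",
    "gaussian_decay",
    "stage1_update",
    "stage2_select",
    "vc_nms",
    "greedy_nms",
    "soft_nms",
]

OverlapKind = Literal["riou", "iou"]


def _overlap_fn(kind: OverlapKind) -> Callable[[Box, Box], float]:
    if kind == "riou":
        return riou
    if kind == "iou":
        return iou
    raise ValueError(f"unknown overlap kind: {kind!r}")


@dataclass(frozen=True)
class VcnmsConfig:
    """Tunable parameters of VC-NMS.

    beta
        Weight of the NCGI term in the composite score; 0.7 balances
        vegetation cover against detector confidence.
    overlap_threshold
        N_t, the RIoU gate: only pairs at or above it can trigger the
        stage-1 overlap attenuation.
    sigma
        Scale of the stage-2 Gaussian decay ``exp(-RIoU^2 / sigma)``.
    final_score_threshold
        Stage-2 retention cutoff on the working score.
    box_threshold
        Pre-filter on raw detector confidence, applied before any scoring.
    attenuation
        Disable to skip the stage-1 overlap penalty entirely.
    per_pair_attenuation
        Apply the stage-1 penalty once per qualifying pair instead of at
        most once per box (non-default interpretation, kept for
        sensitivity studies).
    overlap_measure
        "riou" (default) or "iou" for both the stage-1 gate and the
        stage-2 decay; "iou" reduces stage 2 to classic Soft-NMS geometry.
    oven_gate
        Comparison of overlap counts in the stage-1 gate: "strict"
        (default) penalizes box i only when it has *more* overlapping
        boxes than the later box j, "geq" also fires on equal counts.
        Strict comparison keeps equal-count duplicate stacks untouched in
        stage 1 (they are resolved by the stage-2 decay), which is what
        lets the attenuation single out multi-plant union boxes.
    exg_variant
        Which Excess-Green formula feeds the vegetation mask.
    """

    beta: float = 0.7
    overlap_threshold: float = 0.7
    sigma: float = 0.5
    final_score_threshold: float = 0.1
    box_threshold: float = 0.1
    attenuation: bool = True
    per_pair_attenuation: bool = False
    overlap_measure: OverlapKind = "riou"
    oven_gate: Literal["strict", "geq"] = "strict"
    exg_variant: Literal["raw", "normalized"] = "raw"

    def __post_init__(self) -> None:
        for name in ("beta", "overlap_threshold", "final_score_threshold",
                     "box_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class ScoredCandidateSet:
    """Parallel arrays: boxes B, working scores S, NCGI N, overlap graph O."""

    boxes: list[Box]
    scores: np.ndarray
    ncgi: np.ndarray
    graph: OverlapGraph

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.ncgi = np.asarray(self.ncgi, dtype=np.float64)
        n = len(self.boxes)
        if not (len(self.scores) == len(self.ncgi) == self.graph.n == n):
            raise ValueError("candidate arrays have inconsistent lengths")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite working scores")


@dataclass(frozen=True)
class SuppressedBox:
    box: Box
    reason: Literal["prefiltered", "below-threshold", "decayed", "overlap"]
    final_score: float


@dataclass
class NmsResult:
    """Final detections plus the full suppression record.

    ``kept`` carries the final working scores; ``suppressed`` keeps every
    discarded box with its reason so qualitative before/after comparisons
    can be rendered without re-running the algorithm.
    """

    kept: list[Box]
    suppressed: list[SuppressedBox] = field(default_factory=list)
    trace: dict = field(default_factory=dict)

    @property
    def kept_scores(self) -> list[float]:
        return [b.score for b in self.kept]


def composite_score(ncgi_i: float, score_i: float, beta: float) -> float:
    """beta * NCGI + (1 - beta) * confidence, the stage-1 re-score."""
    return beta * ncgi_i + (1.0 - beta) * score_i


def gaussian_decay(riou_value: float, sigma: float) -> float:
    """exp(-r^2 / sigma): 1 at no overlap, steeply small near full overlap."""
    return math.exp(-(riou_value**2) / sigma)


def _pick_order(boxes: Sequence[Box], scores: np.ndarray) -> list[int]:
    """Descending score; ties broken by larger area, then lower box id."""
    return sorted(
        range(len(boxes)),
        key=lambda i: (-scores[i], -boxes[i].area, boxes[i].id),
    )


def stage1_update(
    candidates: ScoredCandidateSet, config: VcnmsConfig
) -> ScoredCandidateSet:
    """Composite re-scoring followed by the overlap-count attenuation.

    Boxes are ranked by descending composite score; box i is attenuated by
    ``1 - oven_i / max_oven`` if some later-ranked box j satisfies both
    ``overlap(b_i, b_j) >= N_t`` and ``oven_i >= oven_j``.  By default the
    attenuation fires at most once per box; ``per_pair_attenuation``
    multiplies once per qualifying pair instead.  With ``max_oven == 0``
    (no overlaps anywhere) no attenuation occurs.
    """
    boxes = candidates.boxes
    ov = _overlap_fn(config.overlap_measure)
    scores = np.array(
        [
            composite_score(candidates.ncgi[i], candidates.scores[i], config.beta)
            for i in range(len(boxes))
        ],
        dtype=np.float64,
    )
    trace: list[dict] = [
        {"id": b.id, "composite": float(s), "attenuation": 1.0}
        for b, s in zip(boxes, scores)
    ]
    oven = candidates.graph.oven
    max_oven = candidates.graph.max_oven
    if config.attenuation and max_oven > 0:
        order = _pick_order(boxes, scores)
        factor_base = {i: 1.0 - oven[i] / max_oven for i in range(len(boxes))}
        new_scores = scores.copy()
        strict = config.oven_gate == "strict"
        for rank, i in enumerate(order):
            hits = 0
            for j in order[rank + 1 :]:
                count_ok = oven[i] > oven[j] if strict else oven[i] >= oven[j]
                if count_ok and ov(boxes[i], boxes[j]) >= config.overlap_threshold:
                    hits += 1
                    if not config.per_pair_attenuation:
                        break
            if hits:
                factor = factor_base[i] ** hits
                new_scores[i] = scores[i] * factor
                trace[i]["attenuation"] = factor
        scores = new_scores
    return ScoredCandidateSet(
        boxes=boxes, scores=scores, ncgi=candidates.ncgi, graph=candidates.graph
    ), trace


def stage2_select(
    candidates: ScoredCandidateSet, config: VcnmsConfig
) -> NmsResult:
    """Iterative max-score selection with RIoU-Gaussian score decay.

    Repeatedly moves the highest-scoring box into the final set and decays
    every remaining score by ``exp(-overlap(M, b)^2 / sigma)``; stops when
    no remaining score reaches ``final_score_threshold``.
    """
    boxes = candidates.boxes
    scores = candidates.scores.copy()
    ov = _overlap_fn(config.overlap_measure)
    entered_below = scores < config.final_score_threshold
    alive = set(range(len(boxes)))
    kept: list[Box] = []
    suppressed: list[SuppressedBox] = []
    picks: list[dict] = []
    while alive:
        eligible = [i for i in alive if scores[i] >= config.final_score_threshold]
        if not eligible:
            break
        m = min(eligible, key=lambda i: (-scores[i], -boxes[i].area, boxes[i].id))
        alive.discard(m)
        kept.append(boxes[m].with_score(float(scores[m])))
        picks.append({"id": boxes[m].id, "score": float(scores[m])})
        for i in alive:
            scores[i] *= gaussian_decay(ov(boxes[m], boxes[i]), config.sigma)
    for i in sorted(alive):
        reason = "below-threshold" if entered_below[i] else "decayed"
        suppressed.append(SuppressedBox(boxes[i], reason, float(scores[i])))
    return NmsResult(kept=kept, suppressed=suppressed, trace={"stage2_picks": picks})


def prepare_candidates(
    image: RgbImage | np.ndarray,
    boxes: Sequence[Box],
    config: VcnmsConfig,
    mask: VegetationMask | None = None,
) -> tuple[ScoredCandidateSet, list[SuppressedBox], VegetationMask]:
    """Pre-filter by detector confidence, then compute NCGI and overlaps."""
    img = image if isinstance(image, RgbImage) else RgbImage(np.asarray(image))
    for b in boxes:
        if b.x_min >= img.width or b.y_min >= img.height or b.x_max <= 0 or b.y_max <= 0:
            raise ValueError(f"box {b.id} lies entirely outside the image")
    prefiltered = [
        SuppressedBox(b, "prefiltered", b.score)
        for b in boxes
        if b.score < config.box_threshold
    ]
    survivors = [b for b in boxes if b.score >= config.box_threshold]
    if mask is None:
        mask = vegetation_mask(img, variant=config.exg_variant)
    graph = build_overlap_graph(survivors)
    ncgi = ncgi_normalized(survivors, mask, graph)
    cand = ScoredCandidateSet(
        boxes=list(survivors),
        scores=np.array([b.score for b in survivors], dtype=np.float64),
        ncgi=ncgi,
        graph=graph,
    )
    return cand, prefiltered, mask


def vc_nms(
    image: RgbImage | np.ndarray,
    raw_boxes: Sequence[Box],
    config: VcnmsConfig = VcnmsConfig(),
    mask: VegetationMask | None = None,
) -> NmsResult:
    """End-to-end VC-NMS: pre-filter, NCGI, stage 1, stage 2.

    A precomputed ``mask`` may be supplied to avoid repeating the ExG/Otsu
    step when several configurations run on the same image.
    """
    cand, prefiltered, _ = prepare_candidates(image, raw_boxes, config, mask=mask)
    if not cand.boxes:
        return NmsResult(kept=[], suppressed=prefiltered, trace={"stage1": []})
    cand, stage1_trace = stage1_update(cand, config)
    result = stage2_select(cand, config)
    result.suppressed = prefiltered + result.suppressed
    result.trace["stage1"] = stage1_trace
    return result


# ---------------------------------------------------------------------------
# Reference baselines for the comparison harness.
# ---------------------------------------------------------------------------


def greedy_nms(
    boxes: Sequence[Box],
    iou_threshold: float = 0.5,
    overlap: OverlapKind = "iou",
) -> NmsResult:
    """Classic hard NMS: keep the confidence leader, drop overlaps above
    the threshold, repeat."""
    ov = _overlap_fn(overlap)
    remaining = sorted(boxes, key=lambda b: (-b.score, -b.area, b.id))
    kept: list[Box] = []
    suppressed: list[SuppressedBox] = []
    while remaining:
        m = remaining.pop(0)
        kept.append(m)
        still = []
        for b in remaining:
            if ov(m, b) > iou_threshold:
                suppressed.append(SuppressedBox(b, "overlap", b.score))
            else:
                still.append(b)
        remaining = still
    return NmsResult(kept=kept, suppressed=suppressed)


def soft_nms(
    boxes: Sequence[Box],
    mode: Literal["linear", "gaussian"] = "gaussian",
    sigma: float = 0.5,
    linear_threshold: float = 0.3,
    score_threshold: float = 0.1,
    overlap: OverlapKind = "iou",
) -> NmsResult:
    """Soft-NMS with linear or Gaussian decay (confidence-ranked, IoU)."""
    ov = _overlap_fn(overlap)
    blist = list(boxes)
    scores = np.array([b.score for b in blist], dtype=np.float64)
    entered_below = scores < score_threshold
    alive = set(range(len(blist)))
    kept: list[Box] = []
    suppressed: list[SuppressedBox] = []
    while alive:
        eligible = [i for i in alive if scores[i] >= score_threshold]
        if not eligible:
            break
        m = min(eligible, key=lambda i: (-scores[i], -blist[i].area, blist[i].id))
        alive.discard(m)
        kept.append(blist[m].with_score(float(scores[m])))
        for i in alive:
            o = ov(blist[m], blist[i])
            if mode == "gaussian":
                scores[i] *= math.exp(-(o**2) / sigma)
            elif o >= linear_threshold:
                scores[i] *= 1.0 - o
    for i in sorted(alive):
        reason = "below-threshold" if entered_below[i] else "decayed"
        suppressed.append(SuppressedBox(blist[i], reason, float(scores[i])))
    return NmsResult(kept=kept, suppressed=suppressed)
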