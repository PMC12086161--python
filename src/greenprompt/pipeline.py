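"""End-to-end orchestration: detect -> VC-NMS -> prompts -> segment ->
evaluate, behind pluggable backend interfaces, plus the benchmark
harnesses (NMS comparison, point-count sweep, beta sensitivity sweep).

Real foundation-model adapters (an open-set detector for text-prompted
boxes, a ViT feature extractor, a promptable segmenter) plug in through
the same three callables the mock backends implement, so the library's
contracts are fully exercised without any model downloads.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Protocol, Sequence

import numpy as np
import yaml

from .boxes import Box
from .metrics import (
    EvalReport,
    dice,
    ece,
    evaluate_detections,
    mask_iou,
    match,
    s_measure,
    weighted_fmeasure,
)
from .prompts import Embedding, PromptSet, generate_prompt_sets
from .synthetic import (
    MockEmbedder,
    ProposalConfig,
    SyntheticScene,
    generate_proposals,
    mock_segmenter,
)
from .vcnms import NmsResult, VcnmsConfig, greedy_nms, soft_nms, vc_nms
from .vegindex import RgbImage

__all__ = [
    "Detector",
    "Embedder",
    "Segmenter",
    "Backends",
    "RunConfig",
    "InstanceRecord",
    "mock_backends",
    "segment_image",
    "run_nms_on_boxes",
    "run_nms_comparison",
    "run_point_sweep",
    "run_beta_sweep",
    "segmentation_scores",
    "StageError",
]

NMS_METHODS = ("vc", "greedy", "soft-linear", "soft-gaussian")


class StageError(RuntimeError):
    """A backend failure wrapped with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"{stage} backend failed: {cause}")
        self.stage = stage
        self.cause = cause


class Detector(Protocol):
    def __call__(
        self, image: RgbImage, text_prompt: str, box_threshold: float
    ) -> list[Box]: ...


class Embedder(Protocol):
    def __call__(self, region: np.ndarray) -> Embedding: ...


class Segmenter(Protocol):
    def __call__(
        self, image: RgbImage, prompt_set: PromptSet
    ) -> tuple[np.ndarray, float]: ...


@dataclass
class Backends:
    detector: Detector
    embedder: Embedder
    segmenter: Segmenter


def mock_backends(
    scene: SyntheticScene, proposal_config: ProposalConfig | None = None
) -> Backends:
    """Deterministic mock backends bound to one synthetic scene.

    The mock detector replays the scene's generated proposal set (already
    filtered to the requested box threshold), standing in for a
    text-prompted open-set detector.
    """
    pcfg = proposal_config or ProposalConfig(seed=scene.provenance.seed)
    proposals = generate_proposals(scene, pcfg)

    def detector(image: RgbImage, text_prompt: str, box_threshold: float) -> list[Box]:
        return [b for b in proposals if b.score >= box_threshold]

    return Backends(
        detector=detector, embedder=MockEmbedder(), segmenter=mock_segmenter
    )


PromptMode = Literal["both", "box", "points"]


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines a run given its inputs; YAML-round-trip
    serializable.  Defaults follow the fully automatic batch setting:
    beta = 0.7, N_t = 0.7, box_threshold = 0.1, two positive and two
    negative points, text prompt "single vegetable"."""

    vcnms: VcnmsConfig = field(default_factory=VcnmsConfig)
    n_pos: int = 2
    n_neg: int = 2
    text_prompt: str = "single vegetable"
    prompt_mode: PromptMode = "both"
    backend: str = "mock"
    seed: int = 0
    schema_version: int = 1

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        data.pop("schema_version", None)
        vc = VcnmsConfig(**data.pop("vcnms", {}))
        return cls(vcnms=vc, **data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())


@dataclass
class InstanceRecord:
    """One segmented plant instance."""

    mask: np.ndarray
    box: Box
    prompt_set: PromptSet
    confidence: float


def segment_image(
    image: RgbImage | np.ndarray,
    run_config: RunConfig,
    backends: Backends,
) -> list[InstanceRecord]:
    """Full pipeline on one image: one instance record per kept box.

    ``prompt_mode`` ablates the prompt channels: "box" sends the box with
    no points, "points" sends the points with a whole-image box, "both"
    sends both cues.
    """
    img = image if isinstance(image, RgbImage) else RgbImage(np.asarray(image))
    cfg = run_config.vcnms
    try:
        boxes = backends.detector(img, run_config.text_prompt, cfg.box_threshold)
    except Exception as e:  # noqa: BLE001 - wrapped with stage context
        raise StageError("detector", e) from e
    if not boxes:
        return []
    result = vc_nms(img, boxes, cfg)
    if not result.kept:
        return []
    scored = [(b, b.score) for b in result.kept]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prompt_sets = generate_prompt_sets(
                img, scored, backends.embedder,
                n_pos=run_config.n_pos, n_neg=run_config.n_neg,
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("embedder", e) from e
    records = []
    full_box = Box(0.0, 0.0, float(img.width), float(img.height))
    for ps in prompt_sets:
        if run_config.prompt_mode == "box":
            seg_ps = PromptSet(box=ps.box, points=[], y_n=ps.y_n)
        elif run_config.prompt_mode == "points":
            seg_ps = PromptSet(box=full_box, points=ps.points, y_n=ps.y_n)
        else:
            seg_ps = ps
        try:
            mask, conf = backends.segmenter(img, seg_ps)
        except Exception as e:  # noqa: BLE001
            raise StageError("segmenter", e) from e
        records.append(
            InstanceRecord(mask=mask, box=ps.box, prompt_set=ps, confidence=conf)
        )
    return records


def run_nms_on_boxes(
    image: RgbImage | np.ndarray,
    boxes: Sequence[Box],
    method: str,
    config: VcnmsConfig,
) -> NmsResult:
    """Apply one NMS variant to a proposal set (shared pre-filter)."""
    survivors = [b for b in boxes if b.score >= config.box_threshold]
    if method == "vc":
        return vc_nms(image, boxes, config)
    if method == "greedy":
        return greedy_nms(survivors, iou_threshold=0.5)
    if method == "soft-linear":
        return soft_nms(survivors, mode="linear",
                        score_threshold=config.final_score_threshold)
    if method == "soft-gaussian":
        return soft_nms(survivors, mode="gaussian", sigma=config.sigma,
                        score_threshold=config.final_score_threshold)
    raise ValueError(f"unknown NMS method: {method!r}")


def run_nms_comparison(
    scene_proposals: Sequence[tuple[SyntheticScene, Sequence[Box]]],
    methods: Sequence[str] = NMS_METHODS,
    run_config: RunConfig = RunConfig(),
) -> dict[str, EvalReport]:
    """Apply each NMS variant to identical proposal sets and score the
    kept boxes against ground truth (pooled across scenes)."""
    out: dict[str, EvalReport] = {}
    for method in methods:
        pairs = []
        for scene, proposals in scene_proposals:
            kept = run_nms_on_boxes(
                scene.image, proposals, method, run_config.vcnms
            ).kept
            pairs.append((kept, scene.gt_boxes))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[method] = evaluate_detections(pairs)
    return out


def segmentation_scores(
    records: Sequence[InstanceRecord], scene: SyntheticScene
) -> dict[str, float]:
    """Instance-mask quality versus ground truth for one scene.

    Predicted masks are greedily matched to ground-truth masks (mask IoU,
    threshold 0.5, confidence-ranked); unmatched ground truths score 0.
    Dataset-style map metrics (ECE, Sm, wFm) are computed on the union
    probability map against the union ground-truth mask.
    """
    gts = scene.gt_masks
    preds = [r.mask for r in records]
    scores = [r.confidence for r in records]
    per_gt_dice = [0.0] * len(gts)
    per_gt_iou = [0.0] * len(gts)
    if preds:
        table = match(preds, gts, iou_threshold=0.5, iou_kind="mask", scores=scores)
        order = np.argsort(-np.asarray(scores), kind="stable")
        for rank, gt_j in enumerate(table.pred_match):
            if gt_j >= 0:
                p = preds[order[rank]]
                per_gt_dice[gt_j] = dice(p, gts[gt_j])
                per_gt_iou[gt_j] = mask_iou(p, gts[gt_j])
    union_pred = (
        np.any(np.stack(preds), axis=0) if preds
        else np.zeros_like(scene.gt_masks[0]) if gts else np.zeros((1, 1), bool)
    )
    union_gt = np.any(np.stack(gts), axis=0) if gts else np.zeros_like(union_pred)
    prob = union_pred.astype(np.float64)
    return {
        "dice": float(np.mean(per_gt_dice)) if per_gt_dice else 1.0,
        "iou": float(np.mean(per_gt_iou)) if per_gt_iou else 1.0,
        "ece": ece(prob, union_gt),
        "sm": s_measure(prob, union_gt),
        "wfm": weighted_fmeasure(prob, union_gt),
        "n_pred": float(len(preds)),
        "n_gt": float(len(gts)),
    }


def _mean_scores(per_scene: list[dict[str, float]]) -> dict[str, float]:
    keys = per_scene[0].keys() if per_scene else []
    return {k: float(np.mean([s[k] for s in per_scene])) for k in keys}


def run_pipeline_on_scenes(
    scenes: Sequence[SyntheticScene],
    run_config: RunConfig,
    proposal_config: ProposalConfig | None = None,
) -> dict[str, float]:
    """Segment every scene with mock backends; mean mask metrics."""
    per_scene = []
    for scene in scenes:
        backends = mock_backends(scene, proposal_config)
        records = segment_image(scene.image, run_config, backends)
        per_scene.append(segmentation_scores(records, scene))
    return _mean_scores(per_scene)


def run_point_sweep(
    scenes: Sequence[SyntheticScene],
    pos_counts: Sequence[int] = (1, 2, 3, 4, 5),
    neg_counts: Sequence[int] = (1, 2, 3, 4, 5),
    run_config: RunConfig = RunConfig(),
    proposal_config: ProposalConfig | None = None,
) -> np.ndarray:
    """Mean Dice over scenes for each (n_neg, n_pos) grid cell.

    Rows index negative counts, columns positive counts, mirroring the
    usual presentation of point-count ablations.
    """
    out = np.zeros((len(neg_counts), len(pos_counts)))
    for i, nn in enumerate(neg_counts):
        for j, np_ in enumerate(pos_counts):
            cfg = replace(run_config, n_pos=np_, n_neg=nn)
            out[i, j] = run_pipeline_on_scenes(scenes, cfg, proposal_config)["dice"]
    return out


def run_beta_sweep(
    scenes: Sequence[SyntheticScene],
    betas: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    run_config: RunConfig = RunConfig(),
    proposal_config: ProposalConfig | None = None,
) -> dict[float, dict[str, float]]:
    """Pipeline metrics as a function of the NCGI weight beta."""
    out = {}
    for beta in betas:
        cfg = replace(run_config, vcnms=replace(run_config.vcnms, beta=beta))
        out[float(beta)] = run_pipeline_on_scenes(scenes, cfg, proposal_config)
    return out
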