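"""Seeded synthetic vertical-farm scenes, detector pathologies, and mock
backends.

The generator emulates the imaging conditions of stacked hydroponic racks:
green plants of varying scale rendered as clusters of overlapping leaf
ellipses on a granular non-green substrate, with an optional illumination
gradient and the red/purple color casts that auto-white-balance drift
produces under mixed LED/daylight lighting.  Ground-truth instance masks
and tight boxes are exact by construction, and plant/substrate channel
statistics are chosen so the Excess-Green + Otsu step separates vegetation
by a guaranteed margin rather than by luck.

The proposal generator reproduces the redundancy pathologies of an
open-set detector prompted with a generic phrase: jittered near-duplicates
and strictly nested sub-boxes around each plant, union boxes swallowing
adjacent plant groups, and confidence scores biased upward with box area so
union boxes tend to outscore tight single-plant boxes.

Mock embedder/segmenter backends make every downstream module testable
with no model downloads; both are deterministic functions of their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .boxes import Box, iou
from .prompts import Embedding, PromptSet
from .vegindex import RgbImage, excess_green, vegetation_mask

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "ProposalConfig",
    "generate_scene",
    "generate_proposals",
    "mock_embedder",
    "MockEmbedder",
    "mock_segmenter",
]

Tint = Literal["none", "red", "purple"]

# substrate base color (slightly brown: R > G so background ExG < 0)
_BG_COLOR = (120, 105, 95)
# leaf color bands: G dominant by a wide margin over R and B
_LEAF_R = (25, 85)
_LEAF_G = (150, 230)
_LEAF_B = (25, 95)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene; the seed fixes all randomness."""

    width: int = 256
    height: int = 256
    n_plants: int = 8
    plant_radius_range: tuple[int, int] = (10, 22)
    leaves_per_plant: tuple[int, int] = (4, 7)
    overlap: float = 0.0  # 0 = disjoint plants; 1 = centers may coincide
    min_gap: int = 4
    granular_noise: int = 22
    gradient: bool = True
    tint: Tint = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap must be in [0, 1]")
        if self.plant_radius_range[1] * 2 + 8 > min(self.width, self.height):
            raise ValueError("plants do not fit within the canvas")


@dataclass
class SyntheticScene:
    """Image + exact per-plant ground truth + provenance config."""

    image: RgbImage
    gt_masks: list[np.ndarray]
    gt_boxes: list[Box]
    provenance: SceneConfig

    @property
    def n_plants(self) -> int:
        return len(self.gt_boxes)


def _place_plants(cfg: SceneConfig, rng: np.random.Generator):
    """Rejection-sample plant centers/radii honoring the density setting."""
    placed: list[tuple[int, int, int]] = []  # (cx, cy, r)
    for _ in range(cfg.n_plants):
        r = int(rng.integers(cfg.plant_radius_range[0], cfg.plant_radius_range[1] + 1))
        for attempt in range(500):
            cx = int(rng.integers(r + 2, cfg.width - r - 2))
            cy = int(rng.integers(r + 2, cfg.height - r - 2))
            required = [
                (r + pr + cfg.min_gap) * (1.0 - cfg.overlap) for _, _, pr in placed
            ]
            ok = all(
                (cx - px) ** 2 + (cy - py) ** 2 >= req**2
                for (px, py, _), req in zip(placed, required)
            )
            if ok:
                placed.append((cx, cy, r))
                break
        else:
            raise RuntimeError(
                f"infeasible packing: could not place plant {len(placed)} "
                f"after 500 attempts (n_plants={cfg.n_plants})"
            )
    return placed


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render a scene; deterministic (integer arithmetic) for a fixed seed.

    Plants are clusters of overlapping green ellipses confined to a disk of
    the plant radius; the substrate is granular (pixel-wise gray noise,
    which the ExG transform cancels, plus small chromatic noise), with an
    optional linear illumination gradient and a global red/purple channel
    gain mimicking white-balance drift.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width

    img = np.empty((h, w, 3), dtype=np.int64)
    for c, base in enumerate(_BG_COLOR):
        img[..., c] = base
    gray = rng.integers(-config.granular_noise, config.granular_noise + 1, (h, w))
    img += gray[..., None]
    chroma = rng.integers(-8, 9, (h, w, 3))
    img += chroma
    if config.gradient:
        axis = int(rng.integers(0, 2))
        sign = 1 if rng.integers(0, 2) else -1
        ramp = np.linspace(-30, 30, h if axis == 0 else w).astype(np.int64) * sign
        img += ramp[:, None, None] if axis == 0 else ramp[None, :, None]

    owner = np.full((h, w), -1, dtype=np.int64)
    plants = _place_plants(config, rng)
    for idx, (cx, cy, r) in enumerate(plants):
        n_leaves = int(
            rng.integers(config.leaves_per_plant[0], config.leaves_per_plant[1] + 1)
        )
        for _ in range(n_leaves):
            # leaf center within 0.45 r, semi-axes within 0.55 r: the leaf
            # stays inside the plant's disk of radius r
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0, 0.45 * r)
            ly = cy + dist * np.sin(ang)
            lx = cx + dist * np.cos(ang)
            a = rng.uniform(0.30, 0.55) * r
            b = rng.uniform(0.5, 1.0) * a
            rot = rng.uniform(0, np.pi)
            rr, cc = draw_ellipse(ly, lx, a, b, shape=(h, w), rotation=rot)
            color = (
                int(rng.integers(*_LEAF_R)),
                int(rng.integers(*_LEAF_G)),
                int(rng.integers(*_LEAF_B)),
            )
            for c in range(3):
                img[rr, cc, c] = color[c]
            owner[rr, cc] = idx

    if config.tint == "red":
        img[..., 0] = img[..., 0] * 5 // 4
    elif config.tint == "purple":
        img[..., 0] = img[..., 0] * 23 // 20
        img[..., 2] = img[..., 2] * 5 // 4

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    gt_masks, gt_boxes = [], []
    for idx in range(len(plants)):
        m = owner == idx
        if not m.any():  # cannot happen with the size bounds above
            continue
        ys, xs = np.nonzero(m)
        gt_masks.append(m)
        gt_boxes.append(
            Box(
                float(xs.min()),
                float(ys.min()),
                float(xs.max() + 1),
                float(ys.max() + 1),
                score=1.0,
                id=len(gt_boxes),
            )
        )
    return SyntheticScene(
        image=RgbImage(pixels), gt_masks=gt_masks, gt_boxes=gt_boxes,
        provenance=config,
    )


@dataclass(frozen=True)
class ProposalConfig:
    """Detector-proposal pathology model.

    Every ground-truth box yields one slightly *expanded* outer box (each
    side pushed out by up to ``jitter_scale`` of the box size, so the box
    still matches its plant at IoU >= 0.7 while enclosing all of its
    vegetation) and ``n_nested_per_gt`` partial crops strictly nested
    inside it that cut away 10-30% of each side — the nested/partially-
    overlapped duplicates an open-set detector stacks on one plant.  Up to
    ``n_union_boxes`` boxes cover the closest plant pairs.  Scores follow
    ``clip01(base + area_bias * area/max_area + noise)`` with a low base,
    so confidences sit just above a 0.1 detector threshold and the big
    union boxes tend to outscore the tight single-plant boxes.
    """

    jitter_scale: float = 0.08
    n_nested_per_gt: int = 3
    n_union_boxes: int = 2
    score_base_range: tuple[float, float] = (0.16, 0.30)
    area_bias: float = 0.20
    score_noise_sd: float = 0.025
    seed: int = 0


def _outer_box(b: Box, scale: float, rng: np.random.Generator,
               width: int, height: int) -> Box:
    if scale == 0.0:
        return Box(b.x_min, b.y_min, b.x_max, b.y_max)
    # expansion-only jitter: the outer box strictly contains the tight box
    ex = rng.uniform(0.01, max(scale, 0.011), 4)
    return Box(
        max(b.x_min - ex[0] * b.width, 0.0),
        max(b.y_min - ex[1] * b.height, 0.0),
        min(b.x_max + ex[2] * b.width, float(width)),
        min(b.y_max + ex[3] * b.height, float(height)),
    )


def _nested_crop(b: Box, rng: np.random.Generator) -> Box:
    fx0, fx1 = rng.uniform(0.10, 0.30), rng.uniform(0.10, 0.30)
    fy0, fy1 = rng.uniform(0.10, 0.30), rng.uniform(0.10, 0.30)
    return Box(
        b.x_min + fx0 * b.width,
        b.y_min + fy0 * b.height,
        b.x_max - fx1 * b.width,
        b.y_max - fy1 * b.height,
    )


def generate_proposals(
    scene: SyntheticScene, config: ProposalConfig = ProposalConfig()
) -> list[Box]:
    """Redundant detector-style proposals with area-biased scores.

    With ``jitter_scale = 0`` and all pathology counts zero the proposals
    are exactly the ground-truth boxes.  Otherwise each ground-truth box is
    recoverable: at least one proposal has IoU >= 0.7 with it.
    """
    rng = np.random.default_rng(config.seed)
    w, h = scene.image.width, scene.image.height
    raw: list[Box] = []
    for gt in scene.gt_boxes:
        raw.append(_outer_box(gt, config.jitter_scale, rng, w, h))
        for _ in range(config.n_nested_per_gt):
            raw.append(_nested_crop(gt, rng))
    if len(scene.gt_boxes) >= 2 and config.n_union_boxes > 0:
        centers = np.array(
            [[(b.x_min + b.x_max) / 2, (b.y_min + b.y_max) / 2] for b in scene.gt_boxes]
        )
        pairs = sorted(
            (
                (np.hypot(*(centers[i] - centers[j])), i, j)
                for i in range(len(centers))
                for j in range(i + 1, len(centers))
            ),
        )
        for _, i, j in pairs[: config.n_union_boxes]:
            a, b = scene.gt_boxes[i], scene.gt_boxes[j]
            pad = float(rng.uniform(0, 4))
            raw.append(
                Box(
                    max(min(a.x_min, b.x_min) - pad, 0.0),
                    max(min(a.y_min, b.y_min) - pad, 0.0),
                    min(max(a.x_max, b.x_max) + pad, float(scene.image.width)),
                    min(max(a.y_max, b.y_max) + pad, float(scene.image.height)),
                )
            )
    if not raw:
        return []
    max_area = max(b.area for b in raw)
    out = []
    for k, b in enumerate(raw):
        s = (
            rng.uniform(*config.score_base_range)
            + config.area_bias * b.area / max_area
            + rng.normal(0, config.score_noise_sd)
        )
        out.append(replace(b, score=float(np.clip(s, 0.0, 1.0)), id=k))
    return out


# ---------------------------------------------------------------------------
# Mock backends.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MockEmbedder:
    """Deterministic feature extractor standing behind the Embedder
    interface.

    Per-cell features are block means of [ExG+, R, G, B, 32*x_norm,
    32*y_norm], box-smoothed over the grid: green cells of different plants
    point in similar feature directions while substrate cells do not, which
    is the property similarity maps need.
    """

    stride: int = 8

    def __call__(self, region: RgbImage | np.ndarray) -> Embedding:
        pixels = region.pixels if isinstance(region, RgbImage) else np.asarray(region)
        h, w = pixels.shape[:2]
        gh, gw = max(h // self.stride, 1), max(w // self.stride, 1)
        # ExG dominates the feature direction; coordinates enter weakly so
        # similarity is driven by vegetation, tinged by spatial layout
        exg = np.maximum(excess_green(pixels), 0.0) / 255.0
        chans = [exg] + [pixels[..., c] / 255.0 for c in range(3)]
        yn, xn = np.meshgrid(
            np.linspace(0.0, 0.15, h), np.linspace(0.0, 0.15, w), indexing="ij"
        )
        chans += [xn, yn]
        grid = np.zeros((gh, gw, len(chans)))
        ys = np.linspace(0, h, gh + 1).astype(int)
        xs = np.linspace(0, w, gw + 1).astype(int)
        for i in range(gh):
            for j in range(gw):
                block = (slice(ys[i], max(ys[i + 1], ys[i] + 1)),
                         slice(xs[j], max(xs[j + 1], xs[j] + 1)))
                for c, ch in enumerate(chans):
                    grid[i, j, c] = ch[block].mean()
        grid = ndimage.uniform_filter(grid, size=(3, 3, 1), mode="nearest")
        return Embedding(grid=grid, stride=self.stride, region_shape=(h, w))


def mock_embedder(region: RgbImage | np.ndarray, stride: int = 8) -> Embedding:
    """Functional form of :class:`MockEmbedder`."""
    return MockEmbedder(stride=stride)(region)


def mock_segmenter(
    image: RgbImage | np.ndarray, prompt_set: PromptSet
) -> tuple[np.ndarray, float]:
    """Deterministic stand-in for a promptable segmenter.

    Returns the union of vegetation-mask connected components (8-connected)
    inside the prompt box that contain at least one positive point and no
    negative point, as a full-image boolean mask, with confidence equal to
    the fraction of the box's vegetation foreground covered.  No qualifying
    component yields an empty mask with confidence 0.  Honors the
    single-mask contract: exactly one (possibly empty) mask per prompt set.
    """
    pixels = image.pixels if isinstance(image, RgbImage) else np.asarray(image)
    h, w = pixels.shape[:2]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        veg = vegetation_mask(pixels)
    b = prompt_set.box
    x0 = max(int(np.floor(b.x_min)), 0)
    y0 = max(int(np.floor(b.y_min)), 0)
    x1 = min(int(np.ceil(b.x_max)), w)
    y1 = min(int(np.ceil(b.y_max)), h)
    out = np.zeros((h, w), dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return out, 0.0
    crop = veg.mask[y0:y1, x0:x1]
    labels, n = ndimage.label(crop, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return out, 0.0
    pos_labels: set[int] = set()
    neg_labels: set[int] = set()
    for p in prompt_set.points:
        px, py = p.x - x0, p.y - y0
        if not (0 <= px < x1 - x0 and 0 <= py < y1 - y0):
            continue
        lab = int(labels[py, px])
        if lab == 0:
            continue
        (pos_labels if p.label == "positive" else neg_labels).add(lab)
    chosen = pos_labels - neg_labels
    if not chosen:
        return out, 0.0
    sel = np.isin(labels, sorted(chosen))
    out[y0:y1, x0:x1] = sel
    fg_total = int(crop.sum())
    conf = float(sel.sum() / fg_total) if fg_total else 0.0
    return out, conf
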