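"""Point-prompt generation: similarity-map base points + max-distance
enhanced points.

For every detection box surviving VC-NMS, a promptable segmenter benefits
from labeled point cues inside the box.  The highest-composite-score box is
cropped as the *reference* plant; a pooled feature vector over its
vegetation foreground is compared (cosine) against every feature cell of
each box region, giving a similarity map.  The similarity argmax/argmin
become the positive/negative *base* points, and *enhanced* points are
placed at the in-region pixel farthest from the already chosen points of
the same label — positives inside the ExG/Otsu foreground, negatives in
the background — spreading the cues over the whole plant instead of
clustering them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from skimage.transform import resize

from .boxes import Box
from .vegindex import RgbImage, VegetationMask, vegetation_mask

__all__ = [
    "Embedding",
    "SimilarityMap",
    "PointPrompt",
    "PromptSet",
    "select_reference",
    "reference_mask",
    "similarity_map",
    "base_points",
    "max_distance_point",
    "build_prompt_set",
    "generate_prompt_sets",
]


@dataclass(frozen=True)
class Embedding:
    """h x w x c feature grid for an image region.

    ``stride`` is the number of region pixels per grid cell;
    ``region_shape`` the (H, W) pixel size of the embedded region.
    """

    grid: np.ndarray
    stride: int
    region_shape: tuple[int, int]

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.float64)
        if g.ndim != 3 or g.shape[2] < 1:
            raise ValueError(f"expected h x w x c grid, got {g.shape}")
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite features")
        object.__setattr__(self, "grid", g)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(ys, xs) pixel coordinates of grid-cell centers."""
        h, w = self.grid.shape[:2]
        ys = (np.arange(h) + 0.5) * self.region_shape[0] / h
        xs = (np.arange(w) + 0.5) * self.region_shape[1] / w
        return ys, xs


@dataclass(frozen=True)
class SimilarityMap:
    """Region-sized map of cosine similarities in [-1, 1]."""

    values: np.ndarray
    box_id: int = -1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.min() < -1.0 - 1e-9 or v.max() > 1.0 + 1e-9:
            raise ValueError("similarity values outside [-1, 1]")
        object.__setattr__(self, "values", np.clip(v, -1.0, 1.0))

    @property
    def is_constant(self) -> bool:
        return bool(self.values.max() == self.values.min())


@dataclass(frozen=True)
class PointPrompt:
    """A labeled prompt pixel.  Coordinates are integers; whether they are
    region-local or full-image depends on the producing stage (base/max-
    distance operations work region-locally, :func:`build_prompt_set`
    returns full-image coordinates)."""

    x: int
    y: int
    label: Literal["positive", "negative"]
    kind: Literal["base", "enhanced"]

    def shifted(self, dx: int, dy: int) -> "PointPrompt":
        return PointPrompt(self.x + dx, self.y + dy, self.label, self.kind)

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "label": self.label, "kind": self.kind}


@dataclass
class PromptSet:
    """One box plus its labeled points — the contract toward a promptable
    segmenter.  ``y_n`` is the box's composite cover-green score."""

    box: Box
    points: list[PointPrompt] = field(default_factory=list)
    y_n: float = 0.0

    @property
    def positives(self) -> list[PointPrompt]:
        return [p for p in self.points if p.label == "positive"]

    @property
    def negatives(self) -> list[PointPrompt]:
        return [p for p in self.points if p.label == "negative"]

    def to_dict(self) -> dict:
        b = self.box
        return {
            "box": [b.x_min, b.y_min, b.width, b.height],
            "score": b.score,
            "y_n": self.y_n,
            "points": [p.to_dict() for p in self.points],
        }


def select_reference(prompt_boxes: Sequence[tuple[Box, float]]) -> Box:
    """The box with the highest composite score y_n; ties prefer the larger
    area, then the lower box id."""
    if not prompt_boxes:
        raise ValueError("no boxes to select a reference from")
    return min(prompt_boxes, key=lambda t: (-t[1], -t[0].area, t[0].id))[0]


def reference_mask(region: RgbImage | np.ndarray) -> VegetationMask:
    """ExG + Otsu scoped to the cropped reference region."""
    return vegetation_mask(region)


def similarity_map(
    region_embed: Embedding,
    ref_embed: Embedding,
    ref_mask: VegetationMask,
    box_id: int = -1,
    pooling: Literal["mean", "weighted"] = "mean",
) -> SimilarityMap:
    """Cosine similarity of each region cell against the pooled reference.

    The reference vector is the mean of the reference-grid cells whose
    centers fall in the vegetation foreground ("weighted" pools with the
    per-cell foreground fraction instead).  The grid-resolution map is
    bilinearly upsampled to region pixel size.  Zero-norm vectors give 0.
    """
    ref = np.asarray(ref_embed.grid)
    ys, xs = ref_embed.cell_centers()
    yi = np.clip(ys.astype(int), 0, ref_mask.height - 1)
    xi = np.clip(xs.astype(int), 0, ref_mask.width - 1)
    if pooling == "mean":
        inside = ref_mask.mask[np.ix_(yi, xi)]
        if inside.any():
            ref_vec = ref[inside].mean(axis=0)
        else:
            warnings.warn("reference foreground empty; pooling all cells")
            ref_vec = ref.reshape(-1, ref.shape[2]).mean(axis=0)
    else:
        h, w = ref.shape[:2]
        weights = _cell_foreground_fraction(ref_mask, h, w)
        total = weights.sum()
        if total == 0:
            warnings.warn("reference foreground empty; pooling all cells")
            weights = np.ones((h, w))
            total = weights.sum()
        ref_vec = (ref * weights[..., None]).sum(axis=(0, 1)) / total

    grid = np.asarray(region_embed.grid)
    norms = np.linalg.norm(grid, axis=2)
    ref_norm = np.linalg.norm(ref_vec)
    dots = grid @ ref_vec
    denom = norms * ref_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 0.0)
    cos = np.clip(cos, -1.0, 1.0)
    full = resize(
        cos,
        region_embed.region_shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return SimilarityMap(values=np.clip(full, -1.0, 1.0), box_id=box_id)


def _cell_foreground_fraction(mask: VegetationMask, h: int, w: int) -> np.ndarray:
    out = np.zeros((h, w))
    hy = mask.height / h
    wx = mask.width / w
    for i in range(h):
        for j in range(w):
            block = mask.mask[int(i * hy): int((i + 1) * hy) or None,
                              int(j * wx): int((j + 1) * wx) or None]
            out[i, j] = block.mean() if block.size else 0.0
    return out


def base_points(simmap: SimilarityMap) -> tuple[PointPrompt, PointPrompt]:
    """Similarity argmax -> positive base, argmin -> negative base.

    Ties resolve to the smallest row-major index.  A constant map is
    degenerate: the positive falls back to the region center and the
    negative to the (0, 0) corner, with a warning.
    """
    v = simmap.values
    if simmap.is_constant:
        warnings.warn("constant similarity map; falling back to center/corner")
        cy, cx = v.shape[0] // 2, v.shape[1] // 2
        return (
            PointPrompt(cx, cy, "positive", "base"),
            PointPrompt(0, 0, "negative", "base"),
        )
    iy, ix = np.unravel_index(int(np.argmax(v)), v.shape)
    jy, jx = np.unravel_index(int(np.argmin(v)), v.shape)
    return (
        PointPrompt(int(ix), int(iy), "positive", "base"),
        PointPrompt(int(jx), int(jy), "negative", "base"),
    )


def max_distance_point(
    base: PointPrompt | Sequence[PointPrompt], allowed_region: np.ndarray
) -> PointPrompt:
    """The allowed pixel farthest (Euclidean, pixel centers) from the base.

    Given several base points, maximizes the *minimum* distance to the set
    (farthest-point sampling).  Ties resolve to the smallest row-major
    index; an empty region raises so the caller can fall back.
    """
    region = np.asarray(allowed_region, dtype=bool)
    ys, xs = np.nonzero(region)
    if len(ys) == 0:
        raise ValueError("empty allowed region for max-distance point")
    pts = [base] if isinstance(base, PointPrompt) else list(base)
    if not pts:
        raise ValueError("no base points given")
    d2 = np.full(len(ys), np.inf)
    for p in pts:
        d2 = np.minimum(d2, (ys - p.y) ** 2.0 + (xs - p.x) ** 2.0)
    k = int(np.argmax(d2))  # nonzero() order is row-major, so first max wins
    ref = pts[0]
    return PointPrompt(int(xs[k]), int(ys[k]), ref.label, "enhanced")


def _masked_base_points(
    simmap: SimilarityMap, fg: np.ndarray, bg: np.ndarray
) -> tuple[PointPrompt, PointPrompt]:
    """Base points with the label/region contract enforced.

    The positive base is the similarity argmax restricted to the
    vegetation foreground and the negative base the argmin restricted to
    the background, whenever those regions are non-empty; empty regions
    fall back to the unrestricted argmax/argmin of :func:`base_points`.
    """
    v = simmap.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pos, neg = base_points(simmap)
    if fg.any() and not simmap.is_constant:
        masked = np.where(fg, v, -np.inf)
        iy, ix = np.unravel_index(int(np.argmax(masked)), v.shape)
        pos = PointPrompt(int(ix), int(iy), "positive", "base")
    if bg.any() and not simmap.is_constant:
        masked = np.where(bg, v, np.inf)
        jy, jx = np.unravel_index(int(np.argmin(masked)), v.shape)
        neg = PointPrompt(int(jx), int(jy), "negative", "base")
    return pos, neg


def _region_slice(box: Box, height: int, width: int) -> tuple[slice, slice]:
    x0 = max(int(np.floor(box.x_min)), 0)
    y0 = max(int(np.floor(box.y_min)), 0)
    x1 = min(int(np.ceil(box.x_max)), width)
    y1 = min(int(np.ceil(box.y_max)), height)
    return slice(y0, max(y1, y0 + 1)), slice(x0, max(x1, x0 + 1))


def build_prompt_set(
    image: RgbImage | np.ndarray,
    box: Box,
    y_n: float,
    embedder: Callable[[np.ndarray], Embedding],
    ref_embed: Embedding | None = None,
    ref_mask: VegetationMask | None = None,
    n_pos: int = 2,
    n_neg: int = 2,
) -> PromptSet:
    """Assemble a PromptSet for one box (full-image coordinates).

    Base positive/negative points come from the similarity map against the
    reference (the box itself when no reference is given); enhanced
    positives are drawn from the region's ExG/Otsu foreground and enhanced
    negatives from its background by iterated max-distance selection.
    Exactly ``n_pos + n_neg`` points are returned unless the background is
    empty, in which case the negative count is reduced with a warning.
    """
    pixels = image.pixels if isinstance(image, RgbImage) else np.asarray(image)
    h, w = pixels.shape[:2]
    ys, xs = _region_slice(box, h, w)
    region = pixels[ys, xs]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        region_veg = vegetation_mask(region)
    region_embed = embedder(region)
    if ref_embed is None:
        ref_embed, ref_mask = region_embed, region_veg
    if ref_mask is None:
        raise ValueError("ref_embed given without ref_mask")
    simmap = similarity_map(region_embed, ref_embed, ref_mask, box_id=box.id)
    fg = region_veg.mask
    bg = ~region_veg.mask
    pos_base, neg_base = _masked_base_points(simmap, fg, bg)
    positives = [pos_base]
    if not fg.any():
        warnings.warn(f"box {box.id}: empty foreground; center-fallback positives")
        cy, cx = region.shape[0] // 2, region.shape[1] // 2
        fallback = [PointPrompt(cx, cy, "positive", "enhanced")]
        positives = (positives + fallback)[:n_pos]
        while len(positives) < n_pos:
            positives.append(positives[-1])
    else:
        while len(positives) < n_pos:
            positives.append(max_distance_point(positives, fg))
    negatives = [neg_base]
    while len(negatives) < n_neg:
        if not bg.any():
            warnings.warn(f"box {box.id}: empty background; reducing negatives")
            break
        negatives.append(max_distance_point(negatives, bg))
    points = [p.shifted(xs.start, ys.start) for p in positives[:n_pos] + negatives[:n_neg]]
    return PromptSet(box=box, points=points, y_n=float(y_n))


def generate_prompt_sets(
    image: RgbImage | np.ndarray,
    scored_boxes: Sequence[tuple[Box, float]],
    embedder: Callable[[np.ndarray], Embedding],
    n_pos: int = 2,
    n_neg: int = 2,
) -> list[PromptSet]:
    """Prompt sets for all boxes against the shared top-score reference."""
    if not scored_boxes:
        return []
    pixels = image.pixels if isinstance(image, RgbImage) else np.asarray(image)
    ref_box = select_reference(scored_boxes)
    h, w = pixels.shape[:2]
    ys, xs = _region_slice(ref_box, h, w)
    ref_region = pixels[ys, xs]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref_veg = reference_mask(ref_region)
    ref_embed = embedder(ref_region)
    return [
        build_prompt_set(
            pixels, b, y, embedder, ref_embed=ref_embed, ref_mask=ref_veg,
            n_pos=n_pos, n_neg=n_neg,
        )
        for b, y in scored_boxes
    ]
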