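"""Axis-aligned scored boxes, IoU / Relative-IoU, and overlap graphs.

The Relative IoU (RIoU) normalizes the intersection by the *smaller* of the
two box areas instead of the union, so a small box fully nested inside a
large one scores 1.0 regardless of the area ratio.  Overlap counts (``oven``)
feed the multi-plant union-box attenuation in :mod:`greenprompt.vcnms`, and
the overlap adjacency defines the normalization cluster for the cover-green
index in :mod:`greenprompt.vegindex`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Box",
    "OverlapGraph",
    "iou",
    "riou",
    "intersection_area",
    "build_overlap_graph",
    "boxes_to_coco",
    "coco_to_boxes",
    "boxes_to_csv",
    "csv_to_boxes",
]


@dataclass(frozen=True)
class Box:
    """A scored axis-aligned rectangle in continuous pixel coordinates.

    Coordinates follow the half-open pixel convention: a pixel with integer
    index (x, y) belongs to the box iff ``x_min <= x < x_max`` and
    ``y_min <= y < y_max``.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: float = 1.0
    id: int = -1

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def diagonal(self) -> float:
        return float((self.width**2 + self.height**2) ** 0.5)

    def with_score(self, score: float) -> "Box":
        return replace(self, score=score)

    def clipped(self, width: float, height: float) -> "Box":
        """Clip to an image of the given size; raises if nothing remains."""
        return Box(
            max(self.x_min, 0.0),
            max(self.y_min, 0.0),
            min(self.x_max, width),
            min(self.y_max, height),
            self.score,
            self.id,
        )


def intersection_area(a: Box, b: Box) -> float:
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if w <= 0.0 or h <= 0.0:
        return 0.0
    return w * h


def iou(a: Box, b: Box) -> float:
    """Intersection over union; symmetric, in [0, 1]."""
    inter = intersection_area(a, b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def riou(a: Box, b: Box) -> float:
    """Relative IoU: intersection over the smaller box's area.

    Saturates at 1.0 under nesting, which is what makes it sensitive to the
    duplicate nested proposals an open-set detector emits around one plant.
    """
    inter = intersection_area(a, b)
    if inter == 0.0:
        return 0.0
    return inter / min(a.area, b.area)


@dataclass
class OverlapGraph:
    """Adjacency over box ids; an edge exists iff intersection area > 0.

    ``oven[i]`` is the overlap count (degree) of box i in input order;
    ``max_oven`` its maximum.  Touching boxes (shared edge, zero area) do
    not overlap.
    """

    n: int
    neighbors: list[set[int]] = field(default_factory=list)

    @property
    def oven(self) -> list[int]:
        return [len(s) for s in self.neighbors]

    @property
    def max_oven(self) -> int:
        return max((len(s) for s in self.neighbors), default=0)

    def overlap_set(self, i: int, include_self: bool = True) -> set[int]:
        s = set(self.neighbors[i])
        if include_self:
            s.add(i)
        return s


def build_overlap_graph(boxes: Sequence[Box]) -> OverlapGraph:
    """O(N^2) pairwise construction; indices refer to input order."""
    n = len(boxes)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if intersection_area(boxes[i], boxes[j]) > 0.0:
                neighbors[i].add(j)
                neighbors[j].add(i)
    return OverlapGraph(n=n, neighbors=neighbors)


# ---------------------------------------------------------------------------
# Serialization: COCO-detection JSON ([x, y, w, h] + score) and CSV.
# ---------------------------------------------------------------------------


def boxes_to_coco(
    boxes: Iterable[Box], image_id: int = 0, category_id: int = 1
) -> list[dict]:
    out = []
    for b in boxes:
        out.append(
            {
                "image_id": image_id,
                "category_id": category_id,
                "bbox": [b.x_min, b.y_min, b.width, b.height],
                "score": b.score,
                "id": b.id,
            }
        )
    return out


def coco_to_boxes(records: Iterable[dict]) -> list[Box]:
    boxes = []
    for k, r in enumerate(records):
        x, y, w, h = r["bbox"]
        boxes.append(
            Box(x, y, x + w, y + h, float(r.get("score", 1.0)), int(r.get("id", k)))
        )
    return boxes


def boxes_to_csv(boxes: Iterable[Box], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_min", "y_min", "x_max", "y_max", "score", "id"])
        for b in boxes:
            writer.writerow(
                [repr(float(b.x_min)), repr(float(b.y_min)),
                 repr(float(b.x_max)), repr(float(b.y_max)),
                 repr(float(b.score)), b.id]
            )


def csv_to_boxes(path: str | Path) -> list[Box]:
    boxes = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            boxes.append(
                Box(
                    float(row["x_min"]),
                    float(row["y_min"]),
                    float(row["x_max"]),
                    float(row["y_max"]),
                    float(row.get("score", 1.0)),
                    int(row.get("id", -1)),
                )
            )
    return boxes


def save_boxes_json(boxes: Iterable[Box], path: str | Path, image_id: int = 0) -> None:
    with open(path, "w") as fh:
        json.dump(boxes_to_coco(boxes, image_id=image_id), fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_boxes(path: str | Path) -> list[Box]:
    """Load boxes from COCO-detection JSON or CSV, by extension."""
    p = Path(path)
    if p.suffix.lower() == ".csv":
        return csv_to_boxes(p)
    with open(p) as fh:
        data = json.load(fh)
    if isinstance(data, dict) and "annotations" in data:
        data = data["annotations"]
    elif isinstance(data, dict) and "kept" in data:  # nms command output
        data = data["kept"]
    return coco_to_boxes(data)
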