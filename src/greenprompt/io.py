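"""Serialization: COCO-style JSON (boxes + uncompressed RLE masks), PNG
masks/images, and 16-bit ExG inspection maps.

The RLE codec follows the COCO uncompressed convention: column-major
(Fortran) pixel order, counts alternating runs of 0s and 1s and starting
with the 0-run (possibly empty).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .boxes import Box, boxes_to_coco
from .vegindex import RgbImage, VegetationMask

__all__ = [
    "rle_encode",
    "rle_decode",
    "save_mask_png",
    "load_mask_png",
    "save_image_png",
    "load_image",
    "save_exg_png",
    "scene_to_coco",
    "save_json",
]


def rle_encode(mask: np.ndarray) -> dict:
    """Binary mask -> COCO uncompressed RLE (column-major runs)."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    flat = m.reshape(-1, order="F").astype(np.int8)
    if flat.size == 0:
        return {"counts": [], "size": [h, w]}
    change = np.nonzero(np.diff(flat))[0] + 1
    starts = np.concatenate(([0], change, [flat.size]))
    counts = np.diff(starts).tolist()
    if flat[0] == 1:  # counts must start with the zero-run
        counts = [0] + counts
    return {"counts": [int(c) for c in counts], "size": [int(h), int(w)]}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for c in rle["counts"]:
        if val:
            flat[pos: pos + c] = True
        pos += c
        val = not val
    if pos != h * w:
        raise ValueError("RLE counts do not cover the mask")
    return flat.reshape((h, w), order="F")


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def save_image_png(image: RgbImage | np.ndarray, path: str | Path) -> None:
    pixels = image.pixels if isinstance(image, RgbImage) else np.asarray(image)
    iio.imwrite(Path(path), pixels)


def load_image(path: str | Path) -> RgbImage:
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return RgbImage(arr[..., :3])


def save_exg_png(veg: VegetationMask, path: str | Path) -> None:
    """Write the ExG map as a 16-bit PNG (linearly rescaled) for inspection."""
    exg = veg.exg
    lo, hi = float(exg.min()), float(exg.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    iio.imwrite(Path(path), ((exg - lo) * scale).astype(np.uint16))


def scene_to_coco(scene, image_id: int = 0, file_name: str = "scene.png") -> dict:
    """SyntheticScene ground truth -> COCO dataset dict (boxes + RLE)."""
    anns = []
    for k, (box, mask) in enumerate(zip(scene.gt_boxes, scene.gt_masks)):
        anns.append(
            {
                "id": k,
                "image_id": image_id,
                "category_id": 1,
                "bbox": [box.x_min, box.y_min, box.width, box.height],
                "area": float(mask.sum()),
                "iscrowd": 0,
                "segmentation": rle_encode(mask),
            }
        )
    return {
        "images": [
            {
                "id": image_id,
                "file_name": file_name,
                "width": scene.image.width,
                "height": scene.image.height,
            }
        ],
        "annotations": anns,
        "categories": [{"id": 1, "name": "plant"}],
    }


def coco_to_gt(data: dict) -> tuple[list[Box], list[np.ndarray]]:
    """COCO dataset dict -> (gt boxes, gt masks); masks may be empty."""
    boxes, masks = [], []
    for ann in data.get("annotations", []):
        x, y, w, h = ann["bbox"]
        boxes.append(Box(x, y, x + w, y + h, 1.0, int(ann.get("id", len(boxes)))))
        seg = ann.get("segmentation")
        if isinstance(seg, dict) and "counts" in seg:
            masks.append(rle_decode(seg))
    return boxes, masks


def save_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")


def detections_to_coco(boxes: Sequence[Box], image_id: int = 0) -> list[dict]:
    return boxes_to_coco(boxes, image_id=image_id)
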