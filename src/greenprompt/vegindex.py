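"""Excess-Green transform, Otsu binarization and cover-green indices.

Green vegetation on a non-green substrate separates cleanly in the
Excess-Green (ExG) index, classically ``2G - R - B``.  Thresholding the
whole-image ExG map with Otsu's method yields a vegetation mask; the number
of vegetation pixels inside a candidate detection box ("raw cover-green
index", NCGI_raw) measures how much actual plant the box contains, and
normalizing each raw count by the maximum over the box's overlap cluster
gives the Normalized Cover Green Index (NCGI) in [0, 1] used as a
vegetation-aware confidence by VC-NMS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .boxes import Box, OverlapGraph

__all__ = [
    "RgbImage",
    "VegetationMask",
    "excess_green",
    "otsu_binarize",
    "vegetation_mask",
    "ncgi_raw",
    "ncgi_normalized",
]

ExgVariant = Literal["raw", "normalized"]


@dataclass(frozen=True)
class RgbImage:
    """H x W x 3 uint8 image wrapper with shape/range validation."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 image, got shape {p.shape}")
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("empty image")
        if p.dtype != np.uint8:
            if p.min() < 0 or p.max() > 255:
                raise ValueError("intensities outside [0, 255]")
        object.__setattr__(self, "pixels", p.astype(np.uint8, copy=False))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class VegetationMask:
    """Binary vegetation foreground with its ExG map and Otsu threshold.

    ``mask[y, x]`` is True iff ``exg[y, x] > otsu_threshold`` (threshold on
    the 0-255 rescaled ExG scale stored in ``exg_scaled``).
    """

    mask: np.ndarray
    otsu_threshold: float
    exg: np.ndarray

    @property
    def height(self) -> int:
        return int(self.mask.shape[0])

    @property
    def width(self) -> int:
        return int(self.mask.shape[1])

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())


def excess_green(image: RgbImage | np.ndarray, variant: ExgVariant = "raw") -> np.ndarray:
    """Per-pixel Excess-Green map.

    variant="raw": ExG = 2G - R - B on raw 8-bit channels (range [-510, 510]).
    variant="normalized": chromaticity-normalized 2g - r - b with
    r = R/(R+G+B) etc. (range [-1, 2]); black pixels map to 0.
    """
    pixels = image.pixels if isinstance(image, RgbImage) else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {pixels.shape}")
    r = pixels[..., 0].astype(np.float64)
    g = pixels[..., 1].astype(np.float64)
    b = pixels[..., 2].astype(np.float64)
    if variant == "raw":
        return 2.0 * g - r - b
    if variant == "normalized":
        total = r + g + b
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(total > 0, (2.0 * g - r - b) / total, 0.0)
        return out
    raise ValueError(f"unknown ExG variant: {variant!r}")


def _rescale_to_u8(exg_map: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Linearly rescale to [0, 255] and quantize to 256 integer levels."""
    lo = float(exg_map.min())
    hi = float(exg_map.max())
    if hi == lo:
        return np.zeros(exg_map.shape, dtype=np.uint8), lo, hi
    scaled = (exg_map - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8), lo, hi


def otsu_binarize(exg_map: np.ndarray, strict: bool = False) -> VegetationMask:
    """Binarize an ExG map with classical 256-bin histogram Otsu.

    The map is linearly rescaled to [0, 255] and quantized before the
    histogram scan; the returned threshold lives on that rescaled scale.
    A constant map is degenerate: with ``strict=True`` it raises, otherwise
    it yields an all-background mask with a warning (pipeline mode).
    """
    exg_map = np.asarray(exg_map, dtype=np.float64)
    u8, lo, hi = _rescale_to_u8(exg_map)
    if hi == lo:
        if strict:
            raise ValueError("constant ExG map: Otsu threshold undefined")
        warnings.warn("constant ExG map; returning all-background mask")
        return VegetationMask(
            mask=np.zeros(exg_map.shape, dtype=bool), otsu_threshold=255.0, exg=exg_map
        )
    thr = float(threshold_otsu(u8, nbins=256))
    return VegetationMask(mask=u8 > thr, otsu_threshold=thr, exg=exg_map)


def vegetation_mask(image: RgbImage | np.ndarray, variant: ExgVariant = "raw",
                    strict: bool = False) -> VegetationMask:
    """ExG + global Otsu in one step (the standard pipeline entry point)."""
    return otsu_binarize(excess_green(image, variant=variant), strict=strict)


def _pixel_slice(box: Box, height: int, width: int) -> tuple[slice, slice]:
    # Half-open continuous box -> integer pixel-index ranges.  A pixel at
    # integer index x is inside iff x_min <= x < x_max.
    x0 = max(int(np.ceil(box.x_min)), 0)
    y0 = max(int(np.ceil(box.y_min)), 0)
    x1 = min(int(np.ceil(box.x_max)), width)
    y1 = min(int(np.ceil(box.y_max)), height)
    return slice(y0, y1), slice(x0, x1)


def ncgi_raw(mask: VegetationMask, box: Box) -> int:
    """Count of vegetation pixels inside the (clipped) box."""
    ys, xs = _pixel_slice(box, mask.height, mask.width)
    if ys.start >= ys.stop or xs.start >= xs.stop:
        warnings.warn(f"box {box.id} covers no pixels; NCGI_raw = 0")
        return 0
    return int(mask.mask[ys, xs].sum())


def ncgi_normalized(
    boxes: Sequence[Box], mask: VegetationMask, graph: OverlapGraph
) -> np.ndarray:
    """NCGI per box: raw count over the max raw count in its overlap set.

    The overlap set is self-inclusive, so NCGI is always in [0, 1] and each
    overlap cluster's largest-count box scores exactly 1.  A cluster whose
    counts are all zero maps to 0.
    """
    if graph.n != len(boxes):
        raise ValueError("overlap graph inconsistent with box list")
    raw = np.array([ncgi_raw(mask, b) for b in boxes], dtype=np.float64)
    out = np.zeros(len(boxes), dtype=np.float64)
    for i in range(len(boxes)):
        cluster = graph.overlap_set(i, include_self=True)
        denom = max(raw[k] for k in cluster)
        out[i] = raw[i] / denom if denom > 0 else 0.0
    return out
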