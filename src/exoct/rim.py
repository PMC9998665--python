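"""Bony orbital-rim extraction and most-protruding-point localization.

Bone is the only tissue brighter than grayscale 200 on a soft-tissue-window
CT rendering, so the rim mask is obtained by strict thresholding, a
morphological opening that erases thin watermark strokes, and removal of
small connected components (noise blobs). The most protruding rim points
are then found by an extremal scan:

* axial view — the lateral orbital rims sit in the leftmost and rightmost
  thirds of the image; per third, the set pixel with the smallest row
  (most anterior) is the apex;
* sagittal view — the superior and inferior rims sit in the upper and lower
  halves; per half, the set pixel with the smallest column is the apex.

Ties are broken lexicographically (smallest secondary coordinate), which
makes the landmark deterministic on flat bone plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import EmptyRegionError, NoBoneFoundError
from .types import AXIAL, SAGITTAL, CTSlice, as_binary_mask


@dataclass
class RimConfig:
    """Parameters of the rim-extraction stage.

    bone_threshold
        Strict lower bound: a pixel is bone iff intensity ``> bone_threshold``.
    opening_radius
        Radius of the square structuring element, ``(2r+1) x (2r+1)``;
        radius 1 (3x3) is the smallest element that erases width-1 strokes.
    min_component_area
        Connected components (8-connectivity) smaller than this many pixels
        are discarded; components of exactly this area are kept.
    """

    bone_threshold: int = 200
    opening_radius: int = 1
    min_component_area: int = 100

    def __post_init__(self):
        if not 0 <= self.bone_threshold <= 255:
            raise ValueError("bone_threshold must be in [0, 255]")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")
        if self.min_component_area < 0:
            raise ValueError("min_component_area must be >= 0")


@dataclass
class RimApexes:
    """The two most protruding rim points for one slice."""

    view: str
    apex_a: Tuple[int, int]
    apex_b: Tuple[int, int]
    region_a: str
    region_b: str


def threshold_bone(ct: CTSlice, config: RimConfig = RimConfig()) -> np.ndarray:
    """Binary bone mask: intensity strictly greater than the threshold."""
    return np.asarray(ct.pixels) > config.bone_threshold


def morphological_open(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Opening (erosion then dilation) with a square element; radius 0 is identity."""
    mask = as_binary_mask(mask)
    if radius == 0:
        return mask.copy()
    selem = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    return ndi.binary_opening(mask, structure=selem)


def remove_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Keep 8-connected components with area >= min_area (inclusive)."""
    mask = as_binary_mask(mask)
    if min_area <= 1:
        return mask.copy()
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    return areas[labels] >= min_area


def extract_rim_mask(ct: CTSlice, config: RimConfig = RimConfig()) -> np.ndarray:
    """Threshold, open, and component-filter a slice into the rim mask."""
    mask = threshold_bone(ct, config)
    mask = morphological_open(mask, config.opening_radius)
    mask = remove_small_components(mask, config.min_component_area)
    if not mask.any():
        raise NoBoneFoundError("no bone found above threshold")
    return mask


def _lexmin_pixel(region: np.ndarray, primary_axis: int) -> Tuple[int, int]:
    """Set pixel minimizing the primary coordinate, ties by the other one.

    ``primary_axis`` 0 minimizes row first (axial rule), 1 minimizes column
    first (sagittal rule). Returns (row, col) local to ``region``.
    """
    rows, cols = np.nonzero(region)
    if primary_axis == 0:
        order = np.lexsort((cols, rows))
    else:
        order = np.lexsort((rows, cols))
    i = order[0]
    return int(rows[i]), int(cols[i])


def axial_rim_apexes(rim_mask: np.ndarray) -> RimApexes:
    """Most anterior rim pixel in the left and right thirds of an axial mask."""
    rim_mask = as_binary_mask(rim_mask)
    _, width = rim_mask.shape
    left_end = width // 3
    right_start = -(-2 * width // 3)  # ceil(2W/3)
    left = rim_mask[:, :left_end]
    right = rim_mask[:, right_start:]
    if not left.any():
        raise EmptyRegionError("left_third")
    if not right.any():
        raise EmptyRegionError("right_third")
    ra, ca = _lexmin_pixel(left, primary_axis=0)
    rb, cb = _lexmin_pixel(right, primary_axis=0)
    return RimApexes(
        view=AXIAL,
        apex_a=(ra, ca),
        apex_b=(rb, cb + right_start),
        region_a="left_third",
        region_b="right_third",
    )


def sagittal_rim_apexes(rim_mask: np.ndarray) -> RimApexes:
    """Most anterior rim pixel in the upper and lower halves of a sagittal mask."""
    rim_mask = as_binary_mask(rim_mask)
    height, _ = rim_mask.shape
    split = height // 2
    upper = rim_mask[:split, :]
    lower = rim_mask[split:, :]
    if not upper.any():
        raise EmptyRegionError("upper_half")
    if not lower.any():
        raise EmptyRegionError("lower_half")
    ra, ca = _lexmin_pixel(upper, primary_axis=1)
    rb, cb = _lexmin_pixel(lower, primary_axis=1)
    return RimApexes(
        view=SAGITTAL,
        apex_a=(ra, ca),
        apex_b=(rb + split, cb),
        region_a="upper_half",
        region_b="lower_half",
    )


def rim_apexes(rim_mask: np.ndarray, view: str) -> RimApexes:
    """Dispatch to the view-specific apex rule."""
    if view == AXIAL:
        return axial_rim_apexes(rim_mask)
    if view == SAGITTAL:
        return sagittal_rim_apexes(rim_mask)
    raise ValueError(f"unknown view {view!r}")
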