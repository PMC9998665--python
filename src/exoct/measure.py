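"""Corneal-apex localization and the exophthalmos distance itself.

The degree of protrusion is quantified as the perpendicular distance from
the corneal apex to the straight line through the two most protruding
points of the bony orbital rim: on an axial slice one line through both
lateral rims yields one distance per eye; on a sagittal slice the line
joins the superior and inferior rims and yields a single distance.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from . import rim as rim_mod
from .errors import NoEyeFoundError
from .types import (
    AXIAL,
    SAGITTAL,
    CTSlice,
    ExoMeasurement,
    LandmarkSet,
    Point,
    RimLine,
    as_binary_mask,
)


def line_through(p1: Point, p2: Point) -> RimLine:
    """Normalized line ``a*col + b*row + c = 0`` through two (row, col) points.

    Coefficients satisfy ``a**2 + b**2 == 1`` with ``a >= 0`` (and ``b > 0``
    when ``a == 0``), so ``|a*col + b*row + c|`` is the exact perpendicular
    distance in pixels.
    """
    r1, c1 = float(p1[0]), float(p1[1])
    r2, c2 = float(p2[0]), float(p2[1])
    if r1 == r2 and c1 == c2:
        raise ValueError("cannot build a line through coincident points")
    a = r2 - r1
    b = c1 - c2
    norm = math.hypot(a, b)
    a, b = a / norm, b / norm
    if a < 0 or (a == 0 and b < 0):
        a, b = -a, -b
    c = -(a * c1 + b * r1)
    return RimLine(a=a, b=b, c=c)


def point_line_distance(p: Point, line: RimLine) -> float:
    """Perpendicular distance (pixels) from a (row, col) point to a rim line."""
    return line.distance(p)


def corneal_apex_sagittal(eye_mask: np.ndarray) -> Tuple[int, int]:
    """Most anterior eye pixel on a sagittal mask: minimum column, ties by row."""
    eye_mask = as_binary_mask(eye_mask)
    if not eye_mask.any():
        raise NoEyeFoundError("no eye found: empty eye mask")
    rows, cols = np.nonzero(eye_mask)
    i = np.lexsort((rows, cols))[0]
    return int(rows[i]), int(cols[i])


def corneal_apex_axial(eye_mask: np.ndarray) -> Dict[str, Tuple[int, int]]:
    """Per-eye anterior apex on an axial mask.

    The mask is split into 8-connected components; the two largest are kept
    (a warning is issued if more are present) and labeled ``left_eye`` /
    ``right_eye`` by centroid column. Within each component the apex is the
    pixel with minimum row (anterior = top of the image), ties by column.
    """
    eye_mask = as_binary_mask(eye_mask)
    if not eye_mask.any():
        raise NoEyeFoundError("no eye found: empty eye mask")
    labels, n = ndi.label(eye_mask, structure=np.ones((3, 3), dtype=bool))
    if n < 2:
        raise NoEyeFoundError(f"expected two eyes, found {n}")
    areas = ndi.sum_labels(eye_mask, labels, index=np.arange(1, n + 1))
    keep = np.argsort(areas)[::-1][:2] + 1
    if n > 2:
        warnings.warn(
            f"eye mask has {n} components; keeping the 2 largest", stacklevel=2
        )
    apexes = {}
    for lab in keep:
        rows, cols = np.nonzero(labels == lab)
        i = np.lexsort((cols, rows))[0]
        apexes[float(cols.mean())] = (int(rows[i]), int(cols[i]))
    by_centroid = sorted(apexes.items())
    return {"left_eye": by_centroid[0][1], "right_eye": by_centroid[1][1]}


def extract_landmarks(
    ct: CTSlice,
    eye_mask: np.ndarray,
    rim_config: rim_mod.RimConfig = rim_mod.RimConfig(),
) -> LandmarkSet:
    """Run rim extraction and apex localization for one slice."""
    rim_mask = rim_mod.extract_rim_mask(ct, rim_config)
    apexes = rim_mod.rim_apexes(rim_mask, ct.view)
    if ct.view == AXIAL:
        corneal = corneal_apex_axial(eye_mask)
    else:
        corneal = {"eye": corneal_apex_sagittal(eye_mask)}
    return LandmarkSet(
        view=ct.view,
        rim_apex_a=apexes.apex_a,
        rim_apex_b=apexes.apex_b,
        corneal_apexes=corneal,
    )


def measure_landmarks(
    landmarks: LandmarkSet, pixel_spacing_mm: Optional[float] = None
) -> ExoMeasurement:
    """Distances from a landmark set: line through the rim apexes, then the
    perpendicular distance per corneal apex; px -> mm with isotropic spacing."""
    line = line_through(landmarks.rim_apex_a, landmarks.rim_apex_b)
    d_px = {k: point_line_distance(p, line) for k, p in landmarks.corneal_apexes.items()}
    warn: Tuple[str, ...] = ()
    if pixel_spacing_mm is None:
        d_mm = None
        warn = ("pixel spacing unknown: distances reported in pixels only",)
    else:
        d_mm = {k: v * pixel_spacing_mm for k, v in d_px.items()}
    return ExoMeasurement(
        view=landmarks.view,
        line=line,
        landmarks=landmarks,
        distances_px=d_px,
        distances_mm=d_mm,
        pixel_spacing_mm=pixel_spacing_mm,
        warnings=warn,
    )


def measure_slice(
    ct: CTSlice,
    eye_mask: np.ndarray,
    rim_config: rim_mod.RimConfig = rim_mod.RimConfig(),
) -> ExoMeasurement:
    """Full geometric measurement of one slice given its eye mask.

    Composes rim extraction, rim-apex and corneal-apex localization, the
    rim line, and the perpendicular distances; converts to millimetres when
    the slice carries isotropic pixel spacing (anisotropic spacing raises).
    """
    landmarks = extract_landmarks(ct, eye_mask, rim_config)
    spacing = ct.isotropic_spacing()
    meas = measure_landmarks(landmarks, spacing)
    if meas.warnings:
        for w in meas.warnings:
            warnings.warn(w, stacklevel=2)
    return meas
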