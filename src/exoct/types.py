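"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* images are 2D numpy arrays indexed ``[row, col]`` with the origin at the
  top-left, 0-based;
* the canonical intensity scale is 8-bit grayscale ``[0, 255]`` (DICOM input
  is windowed onto this scale before any processing);
* points are ``(row, col)`` tuples, possibly subpixel (float);
* "anterior" is toward the top of an axial image (decreasing row) and toward
  the left of a sagittal image (decreasing column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

AXIAL = "axial"
SAGITTAL = "sagittal"
VIEWS = (AXIAL, SAGITTAL)

Point = Tuple[float, float]


def as_binary_mask(arr: np.ndarray) -> np.ndarray:
    """Coerce an array to a 2D boolean mask, validating shape."""
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {a.shape}")
    return a.astype(bool, copy=False)


@dataclass
class CTSlice:
    """One grayscale CT slice on the canonical 8-bit scale.

    Parameters
    ----------
    pixels
        ``(H, W)`` array of intensities in ``[0, 255]``.
    view
        ``"axial"`` (both eyes visible) or ``"sagittal"`` (one eye).
    pixel_spacing_mm
        Optional ``(row_mm, col_mm)`` in-plane spacing. Millimetre output
        requires isotropic spacing.
    source_id
        Provenance string (file path, phantom id, ...).
    window
        ``(center, width)`` in HU if a display window was applied.
    """

    pixels: np.ndarray
    view: str
    pixel_spacing_mm: Optional[Tuple[float, float]] = None
    source_id: str = ""
    window: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"slice must be 2D, got shape {self.pixels.shape}")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        lo, hi = float(self.pixels.min(initial=0)), float(self.pixels.max(initial=0))
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities must lie in [0, 255], got [{lo}, {hi}]")
        if self.pixel_spacing_mm is not None:
            r, c = self.pixel_spacing_mm
            if not (r > 0 and c > 0):
                raise ValueError("pixel spacing components must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def isotropic_spacing(self) -> Optional[float]:
        """Return the scalar spacing in mm/px, or None if unknown.

        Raises ``ValueError`` for anisotropic spacing: a perpendicular
        distance in mm is undefined when the two axes are scaled differently.
        """
        if self.pixel_spacing_mm is None:
            return None
        r, c = self.pixel_spacing_mm
        if abs(r - c) > 1e-9 * max(r, c):
            raise ValueError(
                f"anisotropic pixel spacing {self.pixel_spacing_mm}: "
                "mm distances require isotropic in-plane spacing"
            )
        return float(r)


@dataclass
class LandmarkSet:
    """Named landmarks for one slice: the rim apex pair and corneal apex(es).

    ``corneal_apexes`` maps ``"left_eye"``/``"right_eye"`` (axial) or
    ``"eye"`` (sagittal) to ``(row, col)`` points.
    """

    view: str
    rim_apex_a: Point
    rim_apex_b: Point
    corneal_apexes: Dict[str, Point]

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")
        if tuple(self.rim_apex_a) == tuple(self.rim_apex_b):
            raise ValueError("rim apexes must be distinct points")
        n = len(self.corneal_apexes)
        want = 2 if self.view == AXIAL else 1
        if n != want:
            raise ValueError(
                f"{self.view} view requires exactly {want} corneal apex(es), got {n}"
            )


@dataclass(frozen=True)
class RimLine:
    """Normalized line ``a*col + b*row + c = 0`` with ``a**2 + b**2 = 1``.

    Sign convention: ``a >= 0``, and ``b > 0`` when ``a == 0``.
    """

    a: float
    b: float
    c: float

    def __post_init__(self):
        n = self.a * self.a + self.b * self.b
        if abs(n - 1.0) > 1e-12:
            raise ValueError(f"line coefficients not normalized: a^2+b^2 = {n}")

    def signed_distance(self, point: Point) -> float:
        r, c = point
        return self.a * c + self.b * r + self.c

    def distance(self, point: Point) -> float:
        return abs(self.signed_distance(point))


@dataclass
class ExoMeasurement:
    """Result of one slice measurement: rim line plus per-eye distances.

    ``distances_px`` maps eye labels to perpendicular distances in pixels;
    ``distances_mm`` is None when the pixel spacing is unknown.
    """

    view: str
    line: RimLine
    landmarks: LandmarkSet
    distances_px: Dict[str, float]
    distances_mm: Optional[Dict[str, float]]
    pixel_spacing_mm: Optional[float]
    warnings: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        for k, v in self.distances_px.items():
            if v < 0:
                raise ValueError(f"negative distance for {k}")
        if self.distances_mm is not None:
            if self.pixel_spacing_mm is None:
                raise ValueError("distances_mm present but pixel spacing unknown")
            for k, v in self.distances_mm.items():
                expect = self.distances_px[k] * self.pixel_spacing_mm
                if abs(v - expect) > 1e-9 * max(1.0, abs(expect)):
                    raise ValueError(f"distance_mm inconsistent with px for {k}")

    def to_dict(self) -> dict:
        return {
            "view": self.view,
            "line": {"a": self.line.a, "b": self.line.b, "c": self.line.c},
            "rim_apex_a": list(self.landmarks.rim_apex_a),
            "rim_apex_b": list(self.landmarks.rim_apex_b),
            "corneal_apexes": {k: list(v) for k, v in self.landmarks.corneal_apexes.items()},
            "distances_px": dict(self.distances_px),
            "distances_mm": None if self.distances_mm is None else dict(self.distances_mm),
            "pixel_spacing_mm": self.pixel_spacing_mm,
            "warnings": list(self.warnings),
        }
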