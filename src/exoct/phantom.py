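"""Synthetic orbital-CT phantoms with analytically known ground truth.

A phantom emulates a soft-tissue-window CT slice rendered to 8-bit
grayscale: a mid-intensity head/tissue ellipse, one or two eye globes as
filled mid-level ellipses, bony orbital-rim arcs as the only structures
brighter than grayscale 200, optional thin watermark strokes at bone
intensity, and additive clipped Gaussian noise. Every sample carries the
true eye and bone masks, the true rim-apex and corneal-apex landmarks, and
the exact (continuous-geometry) apex-to-rim-line distances, so each
pipeline stage can be tested without patient data.

Phantom design notes
--------------------
* True rim apexes sit at integer pixel centers and each bone arc carries a
  small square plateau whose corner is the apex. A bare circular arc is
  tangent to its extremal row/column at a single pixel, which a 3x3 opening
  always removes, shifting the lexicographically tie-broken raster apex
  sideways by O(sqrt(radius)) pixels; the plateau makes the raster landmark
  identical to the continuous one and survives opening.
* ``bone_mask_true`` is the 3x3-opened rasterization of the arcs, and the
  rendered image paints bone exactly there, so thresholding a noise-free
  phantom recovers ``bone_mask_true | stroke_mask`` exactly.
* Watermark strokes are placed at least one pixel clear of bone and globes
  so that the opening can always erase them without leaving nubs fused to
  bone. Real watermarks may cross anatomy; the phantom deliberately avoids
  that regime (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

from .errors import PhantomSpecError
from .measure import line_through, point_line_distance
from .rim import RimConfig, morphological_open, rim_apexes
from .types import AXIAL, SAGITTAL, VIEWS, CTSlice, LandmarkSet, Point

TAB = 5  # side of the square apex plateau, px


@dataclass
class BoneArc:
    """One bony rim wall: an elliptical band plus the apex plateau.

    ``direction`` is the protrusion direction: ``"up"`` (axial lateral rim,
    apex at minimum row) or ``"left"`` (sagittal superior/inferior rim,
    apex at minimum column). The apex of the outer ellipse in that
    direction is the arc's true most-protruding point.
    """

    center: Point
    radii: Tuple[float, float]  # (row semi-axis, col semi-axis)
    half_extent_deg: float
    thickness: float
    direction: str  # 'up' | 'left'

    @property
    def apex(self) -> Point:
        r, c = self.center
        ar, ac = self.radii
        if self.direction == "up":
            return (r - ar, c)
        if self.direction == "left":
            return (r, c - ac)
        raise ValueError(f"unsupported arc direction {self.direction!r}")


@dataclass
class PhantomSpec:
    """Full description of one synthetic slice; see module docstring."""

    view: str
    image_height: int = 256
    image_width: int = 256
    background_level: int = 30
    tissue_level: int = 80
    globe_level: int = 150
    bone_level: int = 230
    globe_centers: List[Point] = field(default_factory=list)
    globe_radii: List[Tuple[float, float]] = field(default_factory=list)
    bone_arcs: List[BoneArc] = field(default_factory=list)
    rim_apex_true: List[Point] = field(default_factory=list)
    tissue_center: Optional[Point] = None
    tissue_radii: Optional[Tuple[float, float]] = None
    n_watermarks: int = 0
    watermark_width: int = 1
    noise_sd: float = 0.0
    pixel_spacing_mm: Optional[float] = 0.5
    seed: int = 0


@dataclass
class PhantomSample:
    """Rendered phantom plus its ground truth."""

    slice: CTSlice
    eye_mask_true: np.ndarray
    bone_mask_true: np.ndarray
    stroke_mask: np.ndarray
    landmarks_true: LandmarkSet
    distance_true_px: Dict[str, float]
    distance_true_mm: Optional[Dict[str, float]]
    spec: PhantomSpec


def true_distance(landmarks: LandmarkSet) -> Dict[str, float]:
    """Exact per-eye apex-to-rim-line distance from continuous landmarks."""
    if landmarks.rim_apex_a is None or landmarks.rim_apex_b is None:
        raise ValueError("landmarks missing a rim apex")
    line = line_through(landmarks.rim_apex_a, landmarks.rim_apex_b)
    if not landmarks.corneal_apexes:
        raise ValueError("landmarks missing a corneal apex")
    return {
        label: point_line_distance(p, line)
        for label, p in landmarks.corneal_apexes.items()
    }


# ---------------------------------------------------------------------------
# rasterization helpers (pixel centers at integer coordinates)

def _grid(h: int, w: int):
    return np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")


def _ellipse_mask(h: int, w: int, center: Point, radii: Tuple[float, float]) -> np.ndarray:
    rr, cc = _grid(h, w)
    ar, ac = radii
    return ((rr - center[0]) / ar) ** 2 + ((cc - center[1]) / ac) ** 2 <= 1.0


def _arc_raster(h: int, w: int, arc: BoneArc) -> np.ndarray:
    """Band between concentric ellipses, limited in angle, plus the plateau."""
    rr, cc = _grid(h, w)
    ar, ac = arc.radii
    t = arc.thickness
    u = (rr - arc.center[0]) / ar
    v = (cc - arc.center[1]) / ac
    rho2 = u * u + v * v
    inner = ((rr - arc.center[0]) / (ar - t)) ** 2 + ((cc - arc.center[1]) / (ac - t)) ** 2
    band = (rho2 <= 1.0) & (inner >= 1.0)
    du, dv = (-1.0, 0.0) if arc.direction == "up" else (0.0, -1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (u * du + v * dv) / np.sqrt(rho2)
    band &= cosang >= np.cos(np.deg2rad(arc.half_extent_deg))

    ap_r, ap_c = arc.apex
    r0, c0 = int(round(ap_r)), int(round(ap_c))
    tab = np.zeros((h, w), dtype=bool)
    tab[max(r0, 0) : r0 + TAB, max(c0, 0) : c0 + TAB] = True
    return band | tab


def _corneal_apexes_true(spec: PhantomSpec) -> Dict[str, Point]:
    out: Dict[str, Point] = {}
    if spec.view == AXIAL:
        order = np.argsort([c[1] for c in spec.globe_centers])
        labels = ["left_eye", "right_eye"]
        for lab, i in zip(labels, order):
            (r, c), (ar, _ac) = spec.globe_centers[i], spec.globe_radii[i]
            out[lab] = (r - ar, c)  # anterior = top of the axial image
    else:
        (r, c), (_ar, ac) = spec.globe_centers[0], spec.globe_radii[0]
        out["eye"] = (r, c - ac)  # anterior = left of the sagittal image
    return out


def validate_spec(spec: PhantomSpec) -> None:
    """Check every spec invariant; raise PhantomSpecError naming the violation."""
    if spec.view not in VIEWS:
        raise PhantomSpecError("view", f"unknown view {spec.view!r}")
    if not (200 < spec.bone_level <= 255):
        raise PhantomSpecError("bone_level", "must be in (200, 255]")
    for name in ("background_level", "tissue_level", "globe_level"):
        v = getattr(spec, name)
        if not (0 <= v <= 200):
            raise PhantomSpecError(name, "must be in [0, 200] so only bone exceeds 200")
    n_globes = 2 if spec.view == AXIAL else 1
    if len(spec.globe_centers) != n_globes or len(spec.globe_radii) != n_globes:
        raise PhantomSpecError("globes", f"{spec.view} view needs {n_globes} globe(s)")
    if len(spec.bone_arcs) != 2 or len(spec.rim_apex_true) != 2:
        raise PhantomSpecError("bone_arcs", "exactly two rim arcs/apexes required")
    for arc, apex in zip(spec.bone_arcs, spec.rim_apex_true):
        ar, ac = arc.apex
        if abs(ar - apex[0]) > 1e-9 or abs(ac - apex[1]) > 1e-9:
            raise PhantomSpecError("rim_apex_true", "apex does not match its bone arc")
        if abs(ar - round(ar)) > 1e-9 or abs(ac - round(ac)) > 1e-9:
            raise PhantomSpecError(
                "rim_apex_integer", "rim apexes must sit at integer pixel centers"
            )
        if arc.thickness < 3:
            raise PhantomSpecError("arc_thickness", "bands thinner than 3 px vanish under opening")
    h, w = spec.image_height, spec.image_width
    (r1, c1), (r2, c2) = spec.rim_apex_true
    if spec.view == AXIAL:
        if not (c1 < w // 3 or c2 < w // 3):
            raise PhantomSpecError("rim_apex_region", "no apex in the left third")
        if not (c1 >= -(-2 * w // 3) or c2 >= -(-2 * w // 3)):
            raise PhantomSpecError("rim_apex_region", "no apex in the right third")
    else:
        if not (min(r1, r2) < h // 2 <= max(r1, r2)):
            raise PhantomSpecError("rim_apex_region", "need one apex per image half")
    # rasterized geometry: globes clear of bone (1 px margin so opening
    # cannot bridge) and clear of each other
    bone_raw = np.zeros((h, w), dtype=bool)
    for arc in spec.bone_arcs:
        bone_raw |= _arc_raster(h, w, arc)
    eye = np.zeros((h, w), dtype=bool)
    for center, radii in zip(spec.globe_centers, spec.globe_radii):
        eye |= _ellipse_mask(h, w, center, radii)
    if (ndi.binary_dilation(bone_raw, np.ones((3, 3), bool)) & eye).any():
        raise PhantomSpecError("globe_bone_overlap", "globes touch or overlap bone arcs")


def _sample_strokes(
    spec: PhantomSpec,
    forbidden: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thin watermark strokes, each 1 px clear of bone, globes and each other."""
    h, w = forbidden.shape
    strokes = np.zeros((h, w), dtype=bool)
    blocked = ndi.binary_dilation(forbidden, np.ones((3, 3), bool))
    placed = 0
    attempts = 0
    while placed < spec.n_watermarks and attempts < 200:
        attempts += 1
        r0, r1 = rng.integers(2, h - 2, size=2)
        c0, c1 = rng.integers(2, w - 2, size=2)
        if abs(int(r1) - int(r0)) + abs(int(c1) - int(c0)) < max(8, h // 8):
            continue
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        cand = np.zeros((h, w), dtype=bool)
        cand[rr, cc] = True
        if spec.watermark_width >= 2:
            cand = ndi.binary_dilation(cand, np.ones((2, 2), bool))
        if (cand & blocked).any():
            continue
        strokes |= cand
        blocked |= ndi.binary_dilation(cand, np.ones((3, 3), bool))
        placed += 1
    return strokes


def render_phantom(spec: PhantomSpec) -> PhantomSample:
    """Rasterize a spec into an image plus ground truth.

    Ground-truth masks are rasterized before noise; landmarks and distances
    come from the continuous geometry, not from the raster.
    """
    validate_spec(spec)
    h, w = spec.image_height, spec.image_width
    rng = np.random.default_rng(spec.seed)

    bone_raw = np.zeros((h, w), dtype=bool)
    for arc in spec.bone_arcs:
        bone_raw |= _arc_raster(h, w, arc)
    bone_true = morphological_open(bone_raw, radius=1)

    eye_true = np.zeros((h, w), dtype=bool)
    for center, radii in zip(spec.globe_centers, spec.globe_radii):
        eye_true |= _ellipse_mask(h, w, center, radii)

    # consistency: the raster landmark must coincide with the stated truth
    raster = rim_apexes(bone_true, spec.view)
    got = {tuple(map(float, raster.apex_a)), tuple(map(float, raster.apex_b))}
    want = {tuple(map(float, p)) for p in spec.rim_apex_true}
    if got != want:
        raise PhantomSpecError(
            "rim_apex_consistency",
            f"raster apexes {got} differ from stated truth {want}",
        )

    img = np.full((h, w), float(spec.background_level))
    if spec.tissue_center is not None and spec.tissue_radii is not None:
        tissue = _ellipse_mask(h, w, spec.tissue_center, spec.tissue_radii)
        img[tissue] = spec.tissue_level
    img[eye_true] = spec.globe_level
    img[bone_true] = spec.bone_level

    strokes = _sample_strokes(spec, bone_true | eye_true, rng)
    img[strokes] = spec.bone_level

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    ct = CTSlice(
        pixels=img,
        view=spec.view,
        pixel_spacing_mm=None
        if spec.pixel_spacing_mm is None
        else (spec.pixel_spacing_mm, spec.pixel_spacing_mm),
        source_id=f"phantom-{spec.view}-seed{spec.seed}",
    )
    apex_a, apex_b = spec.rim_apex_true
    landmarks = LandmarkSet(
        view=spec.view,
        rim_apex_a=tuple(apex_a),
        rim_apex_b=tuple(apex_b),
        corneal_apexes=_corneal_apexes_true(spec),
    )
    d_px = true_distance(landmarks)
    d_mm = (
        None
        if spec.pixel_spacing_mm is None
        else {k: v * spec.pixel_spacing_mm for k, v in d_px.items()}
    )
    return PhantomSample(
        slice=ct,
        eye_mask_true=eye_true,
        bone_mask_true=bone_true,
        stroke_mask=strokes,
        landmarks_true=landmarks,
        distance_true_px=d_px,
        distance_true_mm=d_mm,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# spec builders

def rim_config_for(spec: PhantomSpec) -> RimConfig:
    """Rim-extraction parameters matched to the phantom scale.

    The default minimum component area (100 px at 256x256) scales with the
    image area so that genuine rim arcs are never discarded on small
    phantoms while isolated noise blobs still are.
    """
    s2 = (spec.image_height * spec.image_width) / (256.0 * 256.0)
    return RimConfig(min_component_area=max(10, int(round(100 * s2))))


def random_spec(
    view: str,
    seed: int,
    size: int = 256,
    noise_sd: float = 3.0,
    n_watermarks: int = 2,
    watermark_width: int = 1,
    pixel_spacing_mm: Optional[float] = 0.5,
) -> PhantomSpec:
    """Draw a jittered but anatomically plausible spec for one slice.

    Geometry scales linearly with ``size`` (nominal layout at 256x256,
    0.5 mm/px: axial protrusions of 26-40 px = 13-20 mm per eye, sagittal
    protrusions of 10-22 px = 5-11 mm, matching the clinical ranges of the
    two exophthalmometric parameters). Draws are retried until the spec
    passes validation (globes clear of bone, apexes inside their regions).
    """
    if view not in VIEWS:
        raise ValueError(f"unknown view {view!r}")
    s = size / 256.0
    rng = np.random.default_rng(seed)
    for _ in range(50):
        try:
            spec = _draw_spec(
                view, rng, size, s, noise_sd, n_watermarks, watermark_width,
                pixel_spacing_mm, seed,
            )
            validate_spec(spec)
            return spec
        except PhantomSpecError:
            continue
    raise PhantomSpecError("random_spec", "could not draw a valid spec in 50 tries")


def _draw_spec(view, rng, size, s, noise_sd, n_watermarks, watermark_width,
               pixel_spacing_mm, seed) -> PhantomSpec:
    h = w = size
    thickness = max(3.0, 5.5 * s)
    if view == AXIAL:
        rim_rows = [int(round(108 * s)) + int(rng.integers(-3, 4)) for _ in range(2)]
        c_left = int(round((30 + rng.uniform(0, 10)) * s))
        c_right = w - 1 - int(round((30 + rng.uniform(0, 10)) * s))
        apexes = [(rim_rows[0], c_left), (rim_rows[1], c_right)]
        arcs = []
        for (ar_r, ar_c) in apexes:
            rad = (28 + rng.uniform(0, 6)) * s
            arcs.append(
                BoneArc(
                    center=(ar_r + rad, float(ar_c)),
                    radii=(rad, rad),
                    half_extent_deg=35.0,
                    thickness=thickness,
                    direction="up",
                )
            )
        mean_rim_row = 0.5 * (rim_rows[0] + rim_rows[1])
        centers, radii = [], []
        for side, col0 in ((0, 88.0), (1, 168.0)):
            g_ar = rng.uniform(21, 23) * s
            g_ac = rng.uniform(19, 21) * s
            p = rng.uniform(26, 40) * s
            row = mean_rim_row - p + g_ar
            col = col0 * s + rng.uniform(-3, 3) * s
            centers.append((row, col))
            radii.append((g_ar, g_ac))
        tissue_center = (0.55 * h, 0.5 * w)
        tissue_radii = (0.42 * h, 0.46 * w)
    else:
        rim_cols = [int(round((82 + rng.uniform(0, 8)) * s)) for _ in range(2)]
        r_upper = int(round((66 + rng.uniform(0, 8)) * s))
        r_lower = h - 1 - int(round((66 + rng.uniform(0, 8)) * s))
        apexes = [(r_upper, rim_cols[0]), (r_lower, rim_cols[1])]
        arcs = []
        for (ar_r, ar_c) in apexes:
            rad = (26 + rng.uniform(0, 8)) * s
            arcs.append(
                BoneArc(
                    center=(float(ar_r), ar_c + rad),
                    radii=(rad, rad),
                    half_extent_deg=40.0,
                    thickness=thickness,
                    direction="left",
                )
            )
        mean_rim_col = 0.5 * (rim_cols[0] + rim_cols[1])
        g_ar = rng.uniform(22, 24) * s
        g_ac = rng.uniform(20, 22) * s
        p = rng.uniform(10, 22) * s
        col = mean_rim_col - p + g_ac
        row = 0.5 * h + rng.uniform(-6, 6) * s
        centers, radii = [(row, col)], [(g_ar, g_ac)]
        tissue_center = (0.5 * h, 0.55 * w)
        tissue_radii = (0.46 * h, 0.42 * w)
    return PhantomSpec(
        view=view,
        image_height=h,
        image_width=w,
        globe_centers=centers,
        globe_radii=radii,
        bone_arcs=arcs,
        rim_apex_true=[tuple(map(float, a)) for a in apexes],
        tissue_center=tissue_center,
        tissue_radii=tissue_radii,
        n_watermarks=n_watermarks,
        watermark_width=watermark_width,
        noise_sd=noise_sd,
        pixel_spacing_mm=pixel_spacing_mm,
        seed=seed,
    )


def generate_corpus(
    view: str,
    n: int,
    seed: int,
    size: int = 256,
    **kwargs,
) -> List[PhantomSample]:
    """Render ``n`` independent phantoms; sample i uses seed ``seed + i``."""
    return [
        render_phantom(random_spec(view, seed=int(seed) + i, size=size, **kwargs))
        for i in range(n)
    ]
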