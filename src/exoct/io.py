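"""Readers, writers, DICOM windowing, and the batch pipeline driver.

DICOM input is converted to the canonical 8-bit scale by applying the
rescale slope/intercept and then a linear display window (default soft
tissue, center 40 HU, width 400 HU): values at or below the window floor
map to 0, at or above the ceiling to 255, rounding half away from zero.
PNG input is taken as already windowed; its pixel spacing must come from
the caller.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from . import __version__ as _version
from .errors import ExoctError
from .measure import measure_slice
from .rim import RimConfig
from .types import CTSlice

logger = logging.getLogger(__name__)

SOFT_TISSUE_WINDOW = (40.0, 400.0)  # (center, width) in HU
SCHEMA_VERSION = 1


def window_to_8bit(hu: np.ndarray, center: float, width: float) -> np.ndarray:
    """Linear HU -> [0, 255] display mapping with clipping.

    Monotone by construction; rounding is half away from zero.
    """
    lo = center - width / 2.0
    scaled = (np.asarray(hu, dtype=np.float64) - lo) / width * 255.0
    out = np.floor(np.abs(scaled) + 0.5) * np.sign(scaled)
    return np.clip(out, 0, 255).astype(np.uint8)


def read_png(path, view: str, pixel_spacing_mm: Optional[float] = None) -> CTSlice:
    """Read an 8-bit grayscale PNG as a canonical slice."""
    img = Image.open(path)
    if img.mode != "L":
        raise ExoctError(f"{path}: expected 8-bit grayscale PNG, got mode {img.mode}")
    return CTSlice(
        pixels=np.asarray(img, dtype=np.uint8),
        view=view,
        pixel_spacing_mm=None
        if pixel_spacing_mm is None
        else (pixel_spacing_mm, pixel_spacing_mm),
        source_id=str(path),
    )


def read_dicom(
    path,
    view: str,
    window: Tuple[float, float] = SOFT_TISSUE_WINDOW,
    pixel_spacing_mm: Optional[float] = None,
) -> CTSlice:
    """Read a single-frame grayscale DICOM and window it to 8 bits."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ExoctError(f"{path}: multi-frame or color DICOM is not supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr.astype(np.float64) * slope + intercept
    center, width = window
    pixels = window_to_8bit(hu, center, width)
    spacing = None
    if pixel_spacing_mm is not None:
        spacing = (pixel_spacing_mm, pixel_spacing_mm)
    elif getattr(ds, "PixelSpacing", None) is not None:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return CTSlice(
        pixels=pixels,
        view=view,
        pixel_spacing_mm=spacing,
        source_id=str(path),
        window=(center, width),
    )


def read_ct_image(
    path,
    view: str,
    window: Tuple[float, float] = SOFT_TISSUE_WINDOW,
    pixel_spacing_mm: Optional[float] = None,
) -> CTSlice:
    """Dispatch on extension: ``.dcm`` -> DICOM, anything else -> PNG."""
    p = Path(path)
    if p.suffix.lower() in (".dcm", ".dicom"):
        return read_dicom(p, view, window=window, pixel_spacing_mm=pixel_spacing_mm)
    return read_png(p, view, pixel_spacing_mm=pixel_spacing_mm)


def write_image_png(path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="L").save(path)


def write_mask_png(path, mask: np.ndarray) -> None:
    write_image_png(path, np.asarray(mask, dtype=bool).astype(np.uint8) * 255)


def read_mask_png(path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "L":
        raise ExoctError(f"{path}: expected 8-bit grayscale mask PNG")
    return np.asarray(img) >= 128


def write_phantom_sample(sample, stem) -> Dict[str, str]:
    """Write a phantom as ``<stem>.png`` + ``<stem>_eyemask.png`` + ``<stem>_truth.json``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    img_path = stem.with_suffix(".png")
    mask_path = stem.parent / f"{stem.name}_eyemask.png"
    truth_path = stem.parent / f"{stem.name}_truth.json"
    write_image_png(img_path, sample.slice.pixels)
    write_mask_png(mask_path, sample.eye_mask_true)
    lm = sample.landmarks_true
    truth = {
        "schema_version": SCHEMA_VERSION,
        "software_version": _version,
        "view": sample.spec.view,
        "seed": sample.spec.seed,
        "pixel_spacing_mm": sample.spec.pixel_spacing_mm,
        "rim_apex_true": [list(lm.rim_apex_a), list(lm.rim_apex_b)],
        "corneal_apexes_true": {k: list(v) for k, v in lm.corneal_apexes.items()},
        "distance_true_px": sample.distance_true_px,
        "distance_true_mm": sample.distance_true_mm,
        "spec": {
            "image_height": sample.spec.image_height,
            "image_width": sample.spec.image_width,
            "noise_sd": sample.spec.noise_sd,
            "n_watermarks": sample.spec.n_watermarks,
            "levels": {
                "background": sample.spec.background_level,
                "tissue": sample.spec.tissue_level,
                "globe": sample.spec.globe_level,
                "bone": sample.spec.bone_level,
            },
        },
    }
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"image": str(img_path), "eyemask": str(mask_path), "truth": str(truth_path)}


def write_measurement_json(path, measurement, rim_config: RimConfig) -> None:
    """Measurement result with a full config echo for provenance."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "software_version": _version,
        **measurement.to_dict(),
        "config": {
            "bone_threshold": rim_config.bone_threshold,
            "opening_radius": rim_config.opening_radius,
            "min_component_area": rim_config.min_component_area,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class PipelineResult:
    """Outcome of a batch run: one row per measured eye plus recorded errors."""

    rows: List[dict] = field(default_factory=list)
    errors: List[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def run_pipeline(
    inputs: Sequence[dict],
    segmenter=None,
    rim_config: RimConfig = RimConfig(),
    out_csv=None,
) -> PipelineResult:
    """Segment -> rim -> measure for a batch of slices.

    Each input is a dict with keys ``image`` (path), ``view``, and either
    ``mask`` (path of an eye-mask PNG, used as an oracle) or nothing (the
    ``segmenter`` is applied). Optional ``spacing`` overrides pixel spacing.
    Per-image failures are recorded and skipped; the caller decides whether
    they are fatal.
    """
    from .segmentation import OracleSegmenter, segment_eyes

    result = PipelineResult()
    for item in inputs:
        src = str(item["image"])
        try:
            ct = read_ct_image(
                item["image"], item["view"], pixel_spacing_mm=item.get("spacing")
            )
            if item.get("mask"):
                seg = segment_eyes(ct, OracleSegmenter(read_mask_png(item["mask"])))
            elif segmenter is not None:
                seg = segment_eyes(ct, segmenter)
            else:
                raise ExoctError(f"{src}: no eye mask given and no segmenter loaded")
            meas = measure_slice(ct, seg.mask, rim_config)
            for eye, d_px in meas.distances_px.items():
                result.rows.append(
                    {
                        "image": src,
                        "view": meas.view,
                        "eye": eye,
                        "distance_px": d_px,
                        "distance_mm": None
                        if meas.distances_mm is None
                        else meas.distances_mm[eye],
                        "corneal_apex_row": meas.landmarks.corneal_apexes[eye][0],
                        "corneal_apex_col": meas.landmarks.corneal_apexes[eye][1],
                        "rim_apex_a_row": meas.landmarks.rim_apex_a[0],
                        "rim_apex_a_col": meas.landmarks.rim_apex_a[1],
                        "rim_apex_b_row": meas.landmarks.rim_apex_b[0],
                        "rim_apex_b_col": meas.landmarks.rim_apex_b[1],
                        "segmentation_source": seg.source,
                    }
                )
        except (ExoctError, ValueError) as exc:
            logger.error("%s failed: %s", src, exc)
            result.errors.append({"image": src, "error": str(exc)})
    if out_csv is not None and result.rows:
        fieldnames = list(result.rows[0].keys())
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            writer.writerows(result.rows)
    return result


def read_manifest(path) -> List[dict]:
    """CSV manifest with columns image_path, view[, mask_path, spacing]."""
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                {
                    "image": rec["image_path"],
                    "view": rec["view"],
                    "mask": rec.get("mask_path") or None,
                    "spacing": float(rec["spacing"]) if rec.get("spacing") else None,
                }
            )
    return rows
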