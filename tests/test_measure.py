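"""Landmark geometry and the end-to-end distance measurement."""

import numpy as np
import pytest

from exoct import phantom
from exoct.errors import NoEyeFoundError
from exoct.measure import (
    corneal_apex_axial,
    corneal_apex_sagittal,
    line_through,
    measure_slice,
    point_line_distance,
)
from exoct.types import CTSlice


def _disc(shape, center, radius):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestLine:
    def test_horizontal_vertical_and_oblique(self):
        horiz = line_through((0, 0), (0, 10))
        assert (horiz.a, horiz.b, horiz.c) == pytest.approx((0, 1, 0), abs=1e-12)
        vert = line_through((0, 0), (10, 0))
        assert (vert.a, vert.b, vert.c) == pytest.approx((1, 0, 0), abs=1e-12)
        diag = line_through((0, 0), (10, 10))
        assert diag.a == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert diag.b == pytest.approx(-1 / np.sqrt(2), abs=1e-12)
        for p in ((0, 0), (10, 10)):
            assert abs(diag.signed_distance(p)) < 1e-12

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            line_through((3, 3), (3, 3))

    def test_distance_examples(self):
        horiz = line_through((0, 0), (0, 10))
        assert point_line_distance((5, 0), horiz) == pytest.approx(5.0)
        assert point_line_distance((0, 7), horiz) == pytest.approx(0.0)
        diag = line_through((0, 0), (10, 10))
        assert point_line_distance((3, 4), diag) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_agrees_with_two_point_cross_product_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            r1, c1, r2, c2, r0, c0 = rng.integers(-50, 50, size=6)
            if (r1, c1) == (r2, c2):
                continue
            line = line_through((r1, c1), (r2, c2))
            num = abs((c2 - c1) * (r1 - r0) - (c1 - c0) * (r2 - r1))
            den = np.hypot(r2 - r1, c2 - c1)
            assert point_line_distance((r0, c0), line) == pytest.approx(num / den, abs=1e-9)


class TestCornealApex:
    def test_sagittal_disc_min_col(self):
        mask = _disc((200, 200), (100, 120), 30)
        assert corneal_apex_sagittal(mask) == (100, 90)

    def test_singleton_and_empty(self):
        mask = np.zeros((10, 10), dtype=bool)
        with pytest.raises(NoEyeFoundError):
            corneal_apex_sagittal(mask)
        mask[4, 7] = True
        assert corneal_apex_sagittal(mask) == (4, 7)

    def test_axial_two_discs_labeled_by_column(self):
        mask = _disc((200, 256), (100, 64), 30) | _disc((200, 256), (100, 192), 30)
        apexes = corneal_apex_axial(mask)
        assert apexes == {"left_eye": (70, 64), "right_eye": (70, 192)}

    def test_axial_spurious_component_dropped_with_warning(self):
        mask = _disc((200, 256), (100, 64), 30) | _disc((200, 256), (100, 192), 30)
        mask[5:7, 5:7] = True
        with pytest.warns(UserWarning, match="3 components"):
            apexes = corneal_apex_axial(mask)
        assert apexes["left_eye"] == (70, 64)

    def test_axial_single_component_rejected(self):
        mask = _disc((200, 256), (100, 128), 60)
        with pytest.raises(NoEyeFoundError, match="found 1"):
            corneal_apex_axial(mask)


class TestMeasureSlice:
    @pytest.mark.parametrize("view", ["axial", "sagittal"])
    def test_oracle_masks_recover_truth_within_budget(self, view):
        sample = phantom.render_phantom(
            phantom.random_spec(view, seed=21, noise_sd=0.0, n_watermarks=2)
        )
        meas = measure_slice(
            sample.slice, sample.eye_mask_true, phantom.rim_config_for(sample.spec)
        )
        for eye, d_true in sample.distance_true_px.items():
            assert abs(meas.distances_px[eye] - d_true) <= 1.5

    def test_translation_invariance_of_distances(self, clean_axial_sample):
        sample = clean_axial_sample
        cfg = phantom.rim_config_for(sample.spec)
        base = measure_slice(sample.slice, sample.eye_mask_true, cfg)
        shifted_img = np.roll(np.roll(sample.slice.pixels, 7, axis=0), 11, axis=1)
        shifted_mask = np.roll(np.roll(sample.eye_mask_true, 7, axis=0), 11, axis=1)
        shifted = measure_slice(
            CTSlice(shifted_img, sample.slice.view, sample.slice.pixel_spacing_mm),
            shifted_mask, cfg,
        )
        for eye in base.distances_px:
            assert shifted.distances_px[eye] == pytest.approx(
                base.distances_px[eye], abs=1e-9
            )

    def test_mirror_equivariance_axial(self, clean_axial_sample):
        sample = clean_axial_sample
        cfg = phantom.rim_config_for(sample.spec)
        base = measure_slice(sample.slice, sample.eye_mask_true, cfg)
        mirrored = measure_slice(
            CTSlice(sample.slice.pixels[:, ::-1].copy(), "axial",
                    sample.slice.pixel_spacing_mm),
            sample.eye_mask_true[:, ::-1].copy(), cfg,
        )
        # left and right eyes swap. The lexicographic tie-break picks the
        # other end of a flat apex plateau after mirroring, which translates
        # the (slightly tilted) rim line by a few columns, so equality holds
        # to a small fraction of a pixel rather than exactly.
        assert mirrored.distances_px["left_eye"] == pytest.approx(
            base.distances_px["right_eye"], abs=0.3
        )
        assert mirrored.distances_px["right_eye"] == pytest.approx(
            base.distances_px["left_eye"], abs=0.3
        )

    def test_mm_conversion_and_missing_spacing_warning(self, clean_sagittal_sample):
        sample = clean_sagittal_sample
        cfg = phantom.rim_config_for(sample.spec)
        meas = measure_slice(sample.slice, sample.eye_mask_true, cfg)
        assert meas.distances_mm["eye"] == pytest.approx(
            meas.distances_px["eye"] * 0.5, rel=1e-12
        )
        bare = CTSlice(sample.slice.pixels, "sagittal", pixel_spacing_mm=None)
        with pytest.warns(UserWarning, match="pixel spacing unknown"):
            no_mm = measure_slice(bare, sample.eye_mask_true, cfg)
        assert no_mm.distances_mm is None

    def test_anisotropic_spacing_rejected(self, clean_sagittal_sample):
        sample = clean_sagittal_sample
        ct = CTSlice(sample.slice.pixels, "sagittal", pixel_spacing_mm=(0.5, 0.7))
        with pytest.raises(ValueError, match="anisotropic"):
            measure_slice(ct, sample.eye_mask_true, phantom.rim_config_for(sample.spec))
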