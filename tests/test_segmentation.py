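"""Projection, nucleus detection, rigid stabilization, threshold calibration
algebra and focus measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi
from skimage import transform

import focitrack as ft
from focitrack.segmentation import FrameStats

from conftest import make_two_spot_image


class TestMaxProject:
    def test_single_plane_identity(self):
        img = np.arange(12.0).reshape(1, 3, 4)
        assert np.array_equal(ft.max_project(img), img[0])

    def test_pixelwise_maximum(self):
        a = np.full((2, 2), 3.0)
        b = np.full((2, 2), 7.0)
        out = ft.max_project(np.stack([a, b]))
        assert np.array_equal(out, b)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            ft.max_project(np.empty((0, 4, 4)))


class TestSegmentNuclei:
    def test_two_discs(self):
        img = np.full((120, 200), 10.0)
        yy, xx = np.mgrid[0:120, 0:200]
        img[(xx - 50) ** 2 + (yy - 60) ** 2 < 30**2] = 100.0
        img[(xx - 150) ** 2 + (yy - 60) ** 2 < 30**2] = 100.0
        labels = ft.segment_nuclei(img)
        assert labels.max() == 2

    def test_blank_image_gives_zero_nuclei(self):
        assert ft.segment_nuclei(np.full((50, 50), 7.0)).max() == 0

    def test_border_touching_nucleus_excluded(self):
        img = np.full((100, 100), 10.0)
        yy, xx = np.mgrid[0:100, 0:100]
        img[(xx - 0) ** 2 + (yy - 50) ** 2 < 30**2] = 100.0
        assert ft.segment_nuclei(img).max() == 0


class TestRegistration:
    def test_identity_for_identical_frames(self, clean_timelapse):
        _, stack, _ = clean_timelapse
        st2 = np.stack([stack[0], stack[0].copy()])
        reg, tforms = ft.register_stack(st2)
        assert np.allclose(reg[1], stack[0], atol=1e-6)
        angle, shift = tforms[1]
        assert abs(angle) < 0.2 and np.allclose(shift, 0, atol=0.1)

    def test_translation_recovery(self, clean_timelapse):
        _, stack, _ = clean_timelapse
        f0 = stack[0]
        moved = ndi.shift(f0, (-2.0, 3.0), order=1, cval=float(np.median(f0)))
        reg, _ = ft.register_stack(np.stack([f0, moved]))
        assert np.abs(reg[1] - f0).mean() < 0.2 * np.abs(moved - f0).mean()

    def test_rotation_recovery_within_half_degree(self, clean_timelapse):
        _, stack, _ = clean_timelapse
        f0 = stack[0]
        rot = transform.rotate(f0, 5.0, preserve_range=True, cval=float(np.median(f0)))
        _, tforms = ft.register_stack(np.stack([f0, rot]))
        assert tforms[1][0] == pytest.approx(5.0, abs=0.5)

    def test_constant_frames_warn_and_pass_through(self):
        flat = np.zeros((3, 32, 32))
        with pytest.warns(UserWarning):
            reg, _ = ft.register_stack(flat)
        assert np.array_equal(reg, flat)


class TestThresholdAlgebra:
    def test_frame_stats_hand_arithmetic(self):
        img = np.array([[0.0, 2.0, 4.0, 99.0]])
        mask = np.array([[True, True, True, False]])
        stats = ft.compute_frame_stats(img, mask)
        assert stats.mean_intensity == 2.0
        assert stats.sd_intensity == 2.0  # sample SD, n-1 denominator

    def test_uniform_region_has_zero_sd(self):
        stats = ft.compute_frame_stats(np.full((4, 4), 10.0), np.ones((4, 4), bool))
        assert (stats.mean_intensity, stats.sd_intensity) == (10.0, 0.0)

    def test_tiny_mask_rejected(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        with pytest.raises(ValueError, match=">= 2"):
            ft.compute_frame_stats(np.ones((3, 3)), mask)

    def test_factor_from_manual_threshold(self):
        model = ft.calibrate_threshold_factor(100.0, FrameStats(0, 40.0, 20.0))
        assert model.factor == 3.0

    def test_manual_equal_to_mean_gives_zero_factor(self):
        assert ft.calibrate_threshold_factor(40.0, FrameStats(0, 40.0, 5.0)).factor == 0.0

    def test_zero_sd_rejected_with_frame_named(self):
        with pytest.raises(ValueError, match="frame 0"):
            ft.calibrate_threshold_factor(100.0, FrameStats(0, 40.0, 0.0))

    def test_adaptive_threshold_arithmetic(self):
        model = ft.ThresholdModel(factor=3.0, manual_lower_threshold=80.0)
        assert ft.frame_threshold(FrameStats(1, 50.0, 10.0), model) == 80.0
        zero = ft.ThresholdModel(factor=0.0, manual_lower_threshold=50.0)
        assert ft.frame_threshold(FrameStats(1, 50.0, 10.0), zero) == 50.0

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        manual=st.floats(0.0, 255.0),
        mean=st.floats(0.0, 255.0),
        sd=st.floats(0.1, 120.0),
    )
    def test_calibration_identity(self, manual, mean, sd):
        # applying the calibrated model to its own calibration frame must
        # reproduce the manual threshold (algebraic inverse)
        stats0 = FrameStats(0, mean, sd)
        model = ft.calibrate_threshold_factor(manual, stats0)
        assert ft.frame_threshold(stats0, model) == pytest.approx(manual, abs=1e-9)

    def test_affine_intensity_invariance(self, two_spot_image):
        # rescaling frame and manual threshold by x -> a*x + b leaves the
        # factor and the segmented masks unchanged
        img, _ = two_spot_image
        mask = np.ones(img.shape, bool)
        a, b = 2.0, 10.0
        manual = 60.0
        s0 = ft.compute_frame_stats(img, mask)
        s1 = ft.compute_frame_stats(a * img + b, mask)
        m0 = ft.calibrate_threshold_factor(manual, s0)
        m1 = ft.calibrate_threshold_factor(a * manual + b, s1)
        assert m1.factor == pytest.approx(m0.factor, abs=1e-12)
        l0 = ft.segment_foci(img, ft.frame_threshold(s0, m0), upper_threshold=np.inf)
        l1 = ft.segment_foci(a * img + b, ft.frame_threshold(s1, m1), upper_threshold=np.inf)
        assert np.array_equal(l0 > 0, l1 > 0)


class TestSegmentFoci:
    def test_single_spot_single_label(self):
        img, _ = make_two_spot_image(sep=0.0)
        assert ft.segment_foci(img, 60.0, upper_threshold=np.inf).max() == 1

    def test_no_suprathreshold_pixels_no_foci(self, two_spot_image):
        img, _ = two_spot_image
        assert ft.segment_foci(img, 1e6, upper_threshold=np.inf).max() == 0

    @pytest.mark.parametrize("threshold", [60.0, 90.0])
    def test_watershed_separates_merged_spots(self, two_spot_image, threshold):
        img, centers = two_spot_image
        binary = img >= threshold
        assert ndi.label(binary)[1] == 1  # genuinely merged at this threshold
        labels = ft.segment_foci(img, threshold, upper_threshold=np.inf)
        assert labels.max() == 2

    def test_labels_partition_binary_mask(self, two_spot_image):
        img, _ = two_spot_image
        labels = ft.segment_foci(img, 60.0, upper_threshold=np.inf, min_area=0)
        assert np.array_equal(labels > 0, img >= 60.0)
        for lab in range(1, labels.max() + 1):
            assert (labels == lab).sum() > 0


class TestMeasureFoci:
    def test_square_focus_geometry(self):
        img = np.zeros((6, 6))
        img[2:4, 2:4] = 10.0
        labels = (img > 0).astype(np.int32)
        (focus,) = ft.measure_foci(labels, img, pixel_size=0.5)
        assert focus.area == pytest.approx(1.0)
        assert focus.mean_intensity == 10.0
        assert focus.com == (pytest.approx(1.25), pytest.approx(1.25))
        assert focus.total_intensity == pytest.approx(10.0)

    def test_intensity_weighted_com(self):
        img = np.zeros((1, 2))
        img[0, 0], img[0, 1] = 1.0, 3.0
        labels = np.ones((1, 2), np.int32)
        (focus,) = ft.measure_foci(labels, img, pixel_size=1.0)
        assert focus.com[0] == pytest.approx(0.75)
        geometric = ft.measure_foci(labels, img, 1.0, com_mode="geometric")[0]
        assert geometric.com[0] == pytest.approx(0.5)

    def test_empty_map_gives_empty_list(self):
        assert ft.measure_foci(np.zeros((4, 4), np.int32), np.zeros((4, 4)), 1.0) == []

    def test_detected_coms_match_truth_on_clean_frames(self, clean_timelapse):
        cfg, stack, truth = clean_timelapse
        mask = ft.segment_nuclei(stack[0]) > 0
        stats0 = ft.compute_frame_stats(stack[0], mask)
        model = ft.calibrate_threshold_factor(90.0, stats0)
        for t in range(stack.shape[0]):
            stats = ft.compute_frame_stats(stack[t], mask, frame_index=t)
            labels = ft.segment_foci(stack[t], ft.frame_threshold(stats, model), mask=mask)
            foci = ft.measure_foci(labels, stack[t], cfg.pixel_size, frame_index=t)
            detected = np.array([f.com for f in foci])
            for fid, (x, y) in truth.positions(t).items():
                err_px = np.min(np.hypot(detected[:, 0] - x, detected[:, 1] - y)) / cfg.pixel_size
                assert err_px < 1.0
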