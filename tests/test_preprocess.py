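"""Calibration and digitization: bar detection, rigid fit, template subtraction."""

import numpy as np
import pytest

from paindraw.preprocess import (CalibrationError, PainDrawing,
                                 RigidTransform, detect_bars,
                                 estimate_transform, preprocess_scan,
                                 quality_check,
                                 subtract_template_and_binarize)
from paindraw.synthetic import (NoiseModel, default_probability_tables,
                                render_scanned_sheet, sample_pain_mask)
from paindraw.template import region_mask, render_blank_sheet


def _dice(a, b):
    return 2 * (a & b).sum() / (a.sum() + b.sum())


class TestDetectBars:
    def test_unshifted_scan_centroids_match_bar_centers(self, small_spec):
        scan = render_blank_sheet(small_spec)
        centroids = detect_bars(scan, small_spec)
        np.testing.assert_allclose(centroids, small_spec.bar_centers, atol=0.5)

    def test_shifted_scan_centroids_offset(self, small_spec):
        mask = np.zeros(small_spec.shape, dtype=bool)
        scan, _ = render_scanned_sheet(
            small_spec, mask, NoiseModel.none(), np.random.default_rng(0),
            transform=(5.0, -3.0, 0.0),
        )
        centroids = detect_bars(scan, small_spec)
        offsets = centroids - small_spec.bar_centers
        np.testing.assert_allclose(offsets[:, 0], -3.0, atol=0.5)  # rows = dy
        np.testing.assert_allclose(offsets[:, 1], 5.0, atol=0.5)   # cols = dx

    def test_occluded_bar_raises_calibration_error(self, small_spec):
        scan = render_blank_sheet(small_spec).copy()
        r0, c0, r1, c1 = small_spec.bar_boxes[0]
        scan[r0:r1, c0:c1] = 255  # white-out the first bar
        with pytest.raises(CalibrationError, match="bar 0"):
            detect_bars(scan, small_spec)

    def test_wrong_size_scan_rescaled(self, small_spec):
        from skimage.transform import resize

        scan = render_blank_sheet(small_spec).astype(float)
        h, w = small_spec.shape
        bigger = resize(scan, (int(h * 1.05), int(w * 1.05)), order=1)
        centroids = detect_bars(bigger, small_spec)
        np.testing.assert_allclose(centroids, small_spec.bar_centers, atol=1.0)


class TestEstimateTransform:
    def test_identity(self, small_spec):
        t = estimate_transform(small_spec.bar_centers, small_spec.bar_centers)
        assert (t.dx, t.dy, t.theta) == (0.0, 0.0, 0.0)
        assert t.residual_rms == 0.0

    def test_known_rotation_recovered(self, small_spec):
        centers = small_spec.bar_centers
        theta = np.deg2rad(2.0)
        pivot = centers.mean(axis=0)
        rel = centers - pivot
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        # rotate the (x, y) representation, then back to (row, col)
        detected = (rel[:, ::-1] @ rot.T)[:, ::-1] + pivot
        t = estimate_transform(detected, centers)
        assert abs(t.theta - 2.0) < 0.1
        assert abs(t.dx) < 0.1 and abs(t.dy) < 0.1

    def test_conflicting_two_point_fit_raises(self):
        expected = np.array([[0.0, 0.0], [0.0, 100.0]])
        detected = np.array([[0.0, 0.0], [0.0, 150.0]])  # stretched: not rigid
        with pytest.raises(CalibrationError, match="residual"):
            estimate_transform(detected, expected)

    def test_excessive_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(dx=0, dy=0, theta=20.0)


class TestSubtraction:
    def test_blank_sheet_yields_empty_mask(self, small_spec):
        scan = render_blank_sheet(small_spec)
        mask = subtract_template_and_binarize(
            scan, RigidTransform(0, 0, 0), small_spec)
        assert not mask.any()

    def test_zero_noise_round_trip_near_exact(self, default_spec):
        # at the default resolution the outline-clearing margin does not
        # touch any region, so the zero-noise round trip is near-exact
        eds, _ = default_probability_tables()
        rng = np.random.default_rng(1)
        truth, _ = sample_pain_mask(default_spec, eds, rng)
        scan, _ = render_scanned_sheet(default_spec, truth, NoiseModel.none(),
                                       rng)
        recovered = subtract_template_and_binarize(
            scan, RigidTransform(0, 0, 0), default_spec)
        assert _dice(recovered, truth) >= 0.99

    def test_noisy_round_trip(self, default_spec):
        # speckle 0.001 plus 2 degrees rotation: Dice >= 0.95
        eds, _ = default_probability_tables()
        rng = np.random.default_rng(2)
        truth, _ = sample_pain_mask(default_spec, eds, rng)
        noise = NoiseModel(0.0, 2.0, 0.001, 0)
        scan, _ = render_scanned_sheet(default_spec, truth, noise, rng)
        pd, _ = preprocess_scan(scan, default_spec)
        assert _dice(pd.mask, truth) >= 0.95

    def test_idempotent_on_clean_mask_image(self, small_spec):
        # a mask image with no template and no noise digitizes to itself
        truth = region_mask(small_spec, "foot_plantar")
        img = np.full(small_spec.shape, 255, dtype=np.uint8)
        img[truth] = 0
        recovered = subtract_template_and_binarize(
            img, RigidTransform(0, 0, 0), small_spec)
        np.testing.assert_array_equal(recovered, truth)

    def test_subtraction_never_adds_ink(self, small_spec):
        eds, _ = default_probability_tables()
        rng = np.random.default_rng(3)
        truth, _ = sample_pain_mask(small_spec, eds, rng)
        noise = NoiseModel(3.0, 1.0, 0.0005, 0)
        scan, _ = render_scanned_sheet(small_spec, truth, noise, rng)
        pd, est = preprocess_scan(scan, small_spec)
        # the recovered mask is a subset of the aligned scan's dark pixels:
        # re-running with a huge component threshold keeps it a subset too
        smaller = subtract_template_and_binarize(
            scan, est, small_spec, pivot=small_spec.bar_centers.mean(axis=0)[::-1])
        assert not (pd.mask & ~smaller).any() or (pd.mask == smaller).all()


class TestQualityCheck:
    @pytest.mark.parametrize("area,excluded", [(0, True), (3, True), (1000, False)])
    def test_minimum_marked_area(self, small_spec, area, excluded):
        mask = np.zeros(small_spec.shape, dtype=bool)
        mask.flat[:area] = True
        pd = quality_check(PainDrawing(id="x", label="EDS", mask=mask))
        assert pd.excluded is excluded
        if excluded:
            assert pd.exclusion_reason == "empty_after_preprocessing"

    def test_excluded_requires_reason(self, small_spec):
        with pytest.raises(ValueError):
            PainDrawing(id="x", label="EDS",
                        mask=np.zeros(small_spec.shape, dtype=bool),
                        excluded=True)
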