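"""SSIM difference images, segmentation, and dpix."""

import numpy as np
import pytest
from scipy import ndimage

from arenatrack.roi import GridSpec, PolygonRoi, RoiSet, generate_grid
from arenatrack.ssim import (
    DifferenceImage,
    SsimError,
    SsimParams,
    build_context,
    dpix,
    segment,
    ssim_difference,
)


def naive_ssim_difference(frame, background, params=SsimParams()):
    """Reference implementation recomputing all five mean matrices."""
    x = np.asarray(frame, np.float64)
    y = np.asarray(background, np.float64)
    w = params.win_size
    box = lambda a: ndimage.uniform_filter(a, size=w, mode="reflect")
    mu_x, mu_y = box(x), box(y)
    mu_xx, mu_yy, mu_xy = box(x * x), box(y * y), box(x * y)
    var_x, var_y = mu_xx - mu_x**2, mu_yy - mu_y**2
    cov = mu_xy - mu_x * mu_y
    s = ((2 * mu_x * mu_y + params.c1) * (2 * cov + params.c2)) / (
        (mu_x**2 + mu_y**2 + params.c1) * (var_x + var_y + params.c2)
    )
    return np.clip((1 - s) / 2, 0, 1)


class TestParams:
    @pytest.mark.parametrize("kwargs", [dict(win_size=4), dict(win_size=1),
                                        dict(k1=0.0), dict(k2=-1.0)])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(SsimError):
            SsimParams(**kwargs)

    def test_constants(self):
        p = SsimParams()
        assert p.c1 == pytest.approx((0.01 * 255) ** 2)
        assert p.c2 == pytest.approx((0.03 * 255) ** 2)


class TestContext:
    def test_constant_background_moments(self):
        ctx = build_context(np.full((20, 20), 37, np.uint8))
        assert np.allclose(ctx.mu_y, 37.0)
        assert np.allclose(ctx.mu_yy, 37.0**2)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        bg = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        a, b = build_context(bg), build_context(bg)
        assert np.array_equal(a.mu_y, b.mu_y) and np.array_equal(a.mu_yy, b.mu_yy)

    def test_variance_nonnegative_on_noise(self):
        rng = np.random.default_rng(1)
        ctx = build_context(rng.integers(0, 256, (32, 32)).astype(np.uint8))
        assert (ctx.variance_y() >= -1e-6).all()

    def test_oversized_window_rejected(self):
        with pytest.raises(SsimError):
            build_context(np.zeros((5, 5), np.uint8), SsimParams(win_size=7))


class TestDifference:
    def test_identical_frame_gives_zero(self):
        rng = np.random.default_rng(2)
        bg = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        ctx = build_context(bg)
        d = ssim_difference(bg, ctx)
        assert np.allclose(d.values, 0.0, atol=1e-12)

    def test_constant_images_closed_form(self):
        """Constant frame a vs constant background b: both variances vanish,
        so S = (2ab + C1) / (a^2 + b^2 + C1) everywhere."""
        a, b = 80.0, 200.0
        p = SsimParams()
        ctx = build_context(np.full((16, 16), b, np.uint8))
        d = ssim_difference(np.full((16, 16), a, np.uint8), ctx)
        s = (2 * a * b + p.c1) / (a**2 + b**2 + p.c1)
        assert np.allclose(d.values, (1 - s) / 2, atol=1e-12)

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            bg = rng.integers(0, 256, (48, 40)).astype(np.uint8)
            fr = rng.integers(0, 256, (48, 40)).astype(np.uint8)
            d = ssim_difference(fr, build_context(bg))
            assert np.abs(d.values - naive_ssim_difference(fr, bg)).max() < 1e-10

    def test_matches_skimage_reference(self):
        """Independent library oracle: scikit-image SSIM with a uniform
        window and population covariance."""
        from skimage.metrics import structural_similarity

        rng = np.random.default_rng(4)
        bg = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        fr = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        d = ssim_difference(fr, build_context(bg))
        _, smap = structural_similarity(
            fr, bg, win_size=7, data_range=255, gaussian_weights=False,
            use_sample_covariance=False, full=True,
        )
        assert np.abs(d.values - np.clip((1 - smap) / 2, 0, 1)).max() < 1e-10

    def test_symmetric_in_frame_and_background(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        b = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        d_ab = ssim_difference(a, build_context(b))
        d_ba = ssim_difference(b, build_context(a))
        assert np.allclose(d_ab.values, d_ba.values, atol=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(6)
        bg = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        fr = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        d = ssim_difference(fr, build_context(bg))
        assert d.values.min() >= 0.0 and d.values.max() <= 1.0

    def test_shape_mismatch_rejected(self):
        ctx = build_context(np.zeros((16, 16), np.uint8))
        with pytest.raises(SsimError):
            ssim_difference(np.zeros((16, 17), np.uint8), ctx)


def grid_2x1():
    rs = generate_grid(GridSpec(1, 0, (0, 0, 60, 30)))
    rs.frame_shape = (30, 60)
    return rs


class TestSegment:
    def test_zero_difference_no_detections(self):
        rs = grid_2x1()
        d = DifferenceImage(np.zeros((30, 60)))
        assert segment(d, rs) == []

    def test_single_blob_detected_with_area_and_centroid(self):
        rs = grid_2x1()
        vals = np.zeros((30, 60))
        vals[10:13, 5:9] = 1.0  # 3 x 4 = 12 px^2 in r0c0
        dets = segment(DifferenceImage(vals, 7), rs, min_area=4, max_area=400)
        assert len(dets) == 1
        d = dets[0]
        assert d.roi_id == "r0c0" and d.area == 12 and d.frame_index == 7
        assert d.centroid == pytest.approx((6.5, 11.0))

    def test_largest_passing_component_wins(self):
        rs = grid_2x1()
        vals = np.zeros((30, 60))
        vals[2:5, 2:5] = 1.0     # area 9
        vals[10:15, 10:15] = 1.0  # area 25
        dets = segment(DifferenceImage(vals), rs, min_area=4, max_area=400)
        assert len(dets) == 1
        assert dets[0].area == 25

    def test_area_gate_excludes_too_small_and_too_large(self):
        rs = grid_2x1()
        vals = np.zeros((30, 60))
        vals[5, 5] = 1.0          # area 1 < min_area
        vals[0:20, 31:59] = 1.0   # huge blob in r0c1
        dets = segment(DifferenceImage(vals), rs, min_area=4, max_area=100)
        assert dets == []

    def test_one_detection_per_roi(self):
        rs = grid_2x1()
        vals = np.zeros((30, 60))
        vals[10:13, 5:9] = 1.0    # r0c0
        vals[10:13, 40:44] = 1.0  # r0c1
        dets = segment(DifferenceImage(vals), rs, min_area=4, max_area=400)
        assert sorted(d.roi_id for d in dets) == ["r0c0", "r0c1"]

    def test_roi_reordering_only_changes_attribution(self):
        rs = grid_2x1()
        vals = np.zeros((30, 60))
        vals[10:13, 5:9] = 1.0
        vals[12:16, 45:50] = 1.0
        rs_rev = RoiSet(list(rs)[::-1], rs.frame_shape)
        a = {d.roi_id: (d.centroid, d.area) for d in segment(DifferenceImage(vals), rs)}
        b = {d.roi_id: (d.centroid, d.area) for d in segment(DifferenceImage(vals), rs_rev)}
        assert a == b

    def test_bad_threshold_rejected(self):
        with pytest.raises(SsimError):
            segment(DifferenceImage(np.zeros((30, 60))), grid_2x1(), threshold=1.5)


class TestDpix:
    ROI = PolygonRoi("w", [(0, 0), (20, 0), (20, 20), (0, 20)])

    def test_identical_frames_zero(self):
        f = np.full((20, 20), 100, np.uint8)
        assert dpix(f, f, self.ROI, 10) == 0

    def test_counts_pixels_above_threshold(self):
        a = np.full((20, 20), 100, np.uint8)
        b = a.copy()
        b[3, 3:8] = 111  # 5 pixels changed by threshold + 1
        assert dpix(b, a, self.ROI, 10) == 5

    def test_change_exactly_at_threshold_not_counted(self):
        a = np.full((20, 20), 100, np.uint8)
        b = a.copy()
        b[4, 4] = 110  # delta == threshold -> strict inequality
        assert dpix(b, a, self.ROI, 10) == 0

    def test_changes_outside_roi_ignored(self):
        roi = PolygonRoi("w", [(0, 0), (10, 0), (10, 10), (0, 10)])
        a = np.full((20, 20), 100, np.uint8)
        b = a.copy()
        b[15, 15] = 200
        assert dpix(b, a, roi, 10) == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(SsimError):
            dpix(np.zeros((4, 4), np.uint8), np.zeros((4, 5), np.uint8), self.ROI)
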