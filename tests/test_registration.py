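"""Landmark registration: FOV matching, NCC refinement, TPS fitting, warps."""

import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator

from parstain.core import StainedImage
from parstain.registration import (
    DegenerateLandmarksError,
    LandmarkSet,
    SpatialTransform,
    auto_landmarks,
    fit_transform,
    match_fov,
    refine_landmarks,
    register_pair,
    warp_image,
)


def _texture(rng, shape=(64, 64)):
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(rng.uniform(0, 1, shape), 1.5)


class TestMatchFov:
    def test_equal_pitch_is_identity(self, small_phantom):
        img = small_phantom.he_true
        out = match_fov(small_phantom.contrast, img)
        assert np.array_equal(out.rgb, img.rgb)

    def test_coarser_moving_image_is_upsampled(self, small_phantom):
        coarse = StainedImage(small_phantom.he_true.rgb[::2, ::2], 500.0)
        out = match_fov(small_phantom.contrast, coarse)
        assert out.shape == (128, 128)
        assert out.pixel_pitch_nm == 250.0

    def test_round_trip_dimensions(self, small_phantom):
        img = StainedImage(small_phantom.he_true.rgb, 500.0)
        up = match_fov(small_phantom.contrast, img)  # 250 nm now
        up.pixel_pitch_nm = 125.0
        down = match_fov(small_phantom.contrast, up)
        assert down.shape == img.shape


class TestRefineLandmarks:
    def test_identical_images_leave_landmarks_unchanged(self, rng):
        img = _texture(rng)
        lms = LandmarkSet([[20, 20], [40, 30]], [[20, 20], [40, 30]])
        out = refine_landmarks(img, img, lms, window_px=11, search_px=3)
        assert np.array_equal(out.mov, lms.mov)

    def test_pure_translation_recovered_at_every_point(self, rng):
        img = _texture(rng, (80, 80))
        shifted = np.roll(img, (-2, 3), axis=(0, 1))  # content moves by (3, -2) in (x, y)
        pts = np.array([[25, 25], [40, 30], [30, 45], [50, 50]], dtype=float)
        out = refine_landmarks(img, shifted, LandmarkSet(pts, pts.copy()),
                               window_px=13, search_px=4)
        shifts = out.mov - pts
        assert np.allclose(shifts, [3.0, -2.0])

    def test_zero_search_is_identity(self, rng):
        img = _texture(rng)
        pts = np.array([[30.0, 30.0]])
        out = refine_landmarks(img, np.roll(img, 2, axis=0), LandmarkSet(pts, pts.copy()),
                               window_px=11, search_px=0)
        assert np.array_equal(out.mov, pts)

    def test_flat_window_warns_and_keeps_point(self):
        img = np.zeros((64, 64))
        pts = np.array([[32.0, 32.0]])
        with pytest.warns(UserWarning, match="flat"):
            out = refine_landmarks(img, img, LandmarkSet(pts, pts.copy()),
                                   window_px=11, search_px=2)
        assert np.array_equal(out.mov, pts)


class TestFitTransform:
    def test_identical_pairs_give_identity_map(self, rng):
        pts = rng.uniform(0, 100, (8, 2))
        t = fit_transform(LandmarkSet(pts, pts.copy()))
        assert np.allclose(t(pts), pts, atol=1e-8)

    def test_known_affine_recovered(self, rng):
        a = np.array([[1.1, -0.2], [0.15, 0.9], [3.0, -5.0]])  # (3, 2)
        src = rng.uniform(0, 50, (10, 2))
        dst = np.hstack([src, np.ones((10, 1))]) @ a
        t = fit_transform(LandmarkSet(src, dst), family="affine")
        assert np.allclose(t.parameters["matrix"], a, atol=1e-10)

    def test_tps_interpolates_landmarks_exactly(self, rng):
        src = rng.uniform(0, 100, (12, 2))
        dst = src + rng.normal(0, 3, (12, 2))
        t = fit_transform(LandmarkSet(src, dst))
        assert np.allclose(t(src), dst, atol=1e-8)

    def test_tps_matches_scipy_rbf_oracle_off_landmarks(self, rng):
        """Independent thin-plate oracle: scipy RBFInterpolator."""
        src = rng.uniform(0, 100, (15, 2))
        dst = src + rng.normal(0, 4, (15, 2))
        mine = fit_transform(LandmarkSet(src, dst))
        oracle = RBFInterpolator(src, dst, kernel="thin_plate_spline", degree=1)
        query = rng.uniform(5, 95, (40, 2))
        assert np.allclose(mine(query), oracle(query), atol=1e-8)

    def test_duplicate_points_rejected_with_indices(self):
        src = np.array([[0, 0], [10, 0], [10, 0], [0, 10], [5, 5]], dtype=float)
        with pytest.raises(DegenerateLandmarksError, match=r"\[1, 2\]"):
            fit_transform(LandmarkSet(src, src.copy()))

    def test_collinear_points_rejected(self):
        src = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        with pytest.raises(DegenerateLandmarksError, match="collinear"):
            fit_transform(LandmarkSet(src, src.copy()))

    def test_too_few_points_rejected(self):
        src = np.array([[0, 0], [1, 0]], dtype=float)
        with pytest.raises(DegenerateLandmarksError):
            fit_transform(LandmarkSet(src, src.copy()), family="affine")

    def test_yaml_round_trip_preserves_mapping(self, tmp_path, rng):
        src = rng.uniform(0, 100, (8, 2))
        dst = src + rng.normal(0, 2, (8, 2))
        t = fit_transform(LandmarkSet(src, dst))
        t.save(tmp_path / "t.yaml")
        back = SpatialTransform.load(tmp_path / "t.yaml")
        query = rng.uniform(0, 100, (20, 2))
        assert np.allclose(back(query), t(query))


class TestWarpImage:
    def test_identity_transform_preserves_image(self, small_phantom):
        out = warp_image(small_phantom.he_true, SpatialTransform("identity"),
                         small_phantom.he_true.shape)
        assert np.allclose(out.rgb, small_phantom.he_true.rgb)
        assert not out.oob_mask.any()

    def test_pure_translation_shifts_and_flags_margin(self, small_phantom):
        shift = fit_transform(
            LandmarkSet(
                np.array([[0, 0], [100, 0], [0, 100]], dtype=float),
                np.array([[10, 0], [110, 0], [10, 100]], dtype=float),
            ),
            family="affine",
        )
        out = warp_image(small_phantom.he_true, shift, small_phantom.he_true.shape)
        src = small_phantom.he_true.rgb
        assert np.allclose(out.rgb[:, :-10], src[:, 10:], atol=1e-9)
        assert out.oob_mask[:, -10:].all()
        assert np.allclose(out.rgb[:, -10:], 1.0)  # white H&E background fill


class TestEndToEnd:
    def test_register_pair_recovers_phantom_warp(self, medium_phantom):
        """Refine + fit + warp on a 256 px phantom: sub-pixel mean landmark
        residual and interior error within 2% of range."""
        s = medium_phantom
        registered, transform, lms = register_pair(
            s.contrast, s.he_moving, search_px=8, grid_step=32
        )
        tinv = fit_transform(LandmarkSet(s.landmarks_true.mov, s.landmarks_true.ref))
        resid = np.linalg.norm(tinv(lms.mov) - lms.ref, axis=1)
        assert resid.mean() <= 0.5
        interior = np.s_[16:-16, 16:-16]
        mae = np.abs(registered.rgb[interior] - s.he_true.rgb[interior]).mean()
        assert mae <= 0.02

    def test_auto_landmarks_avoid_flat_regions(self, small_phantom):
        chan = small_phantom.contrast.channels[0]
        lms = auto_landmarks(chan, grid_step=16, window_px=15, min_local_sd=0.02)
        assert len(lms) >= 4
        half = 7
        for x, y in lms.ref:
            win = chan[int(y) - half : int(y) + half + 1, int(x) - half : int(x) + half + 1]
            assert win.std() >= 0.02
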