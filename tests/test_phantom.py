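"""Phantom generator: determinism, channel semantics, forward models."""

import numpy as np
import pytest

from parstain.phantom import (
    DEFAULT_STAIN_VECTORS,
    InvalidSpecError,
    PhantomSpec,
    apply_misregistration,
    emit_scan_stream,
    render_he,
    sample_phantom,
)
from parstain.registration import warp_image


class TestPhantomSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"height_px": 0},
            {"width_px": -3},
            {"pixel_pitch_nm": 0.0},
            {"nuclei_density": -1.0},
            {"noise_sd": (0.5, 1.5, 0.0)},
            {"warp_amplitude_px": -2.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            PhantomSpec(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        spec = PhantomSpec(height_px=64, width_px=48, seed=9)
        spec.save(tmp_path / "spec.yaml")
        assert PhantomSpec.load(tmp_path / "spec.yaml") == spec


class TestSamplePhantom:
    def test_seeded_determinism_bit_identical(self):
        spec = PhantomSpec(height_px=64, width_px=64, seed=11)
        a = sample_phantom(spec)
        b = sample_phantom(spec)
        assert np.array_equal(a.contrast.channels, b.contrast.channels)
        assert np.array_equal(a.he_true.rgb, b.he_true.rgb)
        assert np.array_equal(a.he_moving.rgb, b.he_moving.rgb)
        assert np.array_equal(a.pulse_stream.features, b.pulse_stream.features)
        assert np.array_equal(a.landmarks_true.ref, b.landmarks_true.ref)

    def test_shapes_and_pitch_shared(self, small_phantom):
        s = small_phantom
        assert s.contrast.shape == s.he_true.shape == (128, 128)
        assert s.contrast.pixel_pitch_nm == s.he_true.pixel_pitch_nm

    def test_concentrations_nonnegative_and_nuclear_support(self, small_phantom):
        s = small_phantom
        assert s.c_nuclear.min() >= 0 and s.c_extranuclear.min() >= 0
        # c_n > 0 exactly on drawn nuclei; no background leakage
        assert (s.c_nuclear > 0).sum() > 0
        assert s.n_nuclei > 0

    def test_no_nuclei_channel_depends_only_on_extranuclear(self):
        spec = PhantomSpec(
            height_px=96, width_px=96, nuclei_density=0.0,
            noise_sd=(0.0, 0.0, 0.0), seed=5,
        )
        s = sample_phantom(spec)
        assert s.n_nuclei == 0
        nonrad = s.contrast.channels[0]
        quiet = s.c_extranuclear == 0
        if quiet.any():
            assert nonrad[quiet].max() == 0.0
        # elsewhere the channel is pure cross-talk from c_e
        assert np.allclose(nonrad, np.clip(0.09 * s.c_extranuclear, 0, 1))

    def test_nucleus_count_is_poisson_with_stated_mean(self):
        """Mean count over replicates within 3 SE of density*area/1e4."""
        density, n_rep = 5.0, 300
        counts = np.empty(n_rep)
        for i in range(n_rep):
            spec = PhantomSpec(
                height_px=200, width_px=200, nuclei_density=density,
                fiber_count=0, vessel_count=0, noise_sd=(0, 0, 0),
                warp_amplitude_px=0.0, seed=1000 + i,
            )
            counts[i] = sample_phantom(spec).n_nuclei
        expected = density * 200 * 200 / 1e4  # 20
        se = np.sqrt(expected / n_rep)
        assert abs(counts.mean() - expected) < 3 * se

    def test_channel_separation_without_noise(self, clean_phantom):
        """Non-radiative tracks the nuclear map more than the extranuclear."""
        s = clean_phantom
        nonrad = s.contrast.channels[0].ravel()
        r_n = np.corrcoef(nonrad, s.c_nuclear.ravel())[0, 1]
        r_e = np.corrcoef(nonrad, s.c_extranuclear.ravel())[0, 1]
        assert r_n > r_e


class TestRenderHE:
    def test_zero_concentration_is_white(self):
        img = render_he(np.zeros((4, 4)), np.zeros((4, 4)))
        assert np.allclose(img.rgb, 1.0)

    def test_beer_lambert_closed_form(self):
        c_n = np.ones((2, 2))
        c_e = np.zeros((2, 2))
        stains = np.array([[0.65, 0.70, 0.29], [0.07, 0.99, 0.11]])
        img = render_he(c_n, c_e, stain_vectors=stains, doses=(1.0, 1.0))
        assert np.allclose(img.rgb[0, 0], np.exp(-np.array([0.65, 0.70, 0.29])))

    def test_od_linear_in_concentration(self, rng):
        c_n = rng.uniform(0, 1, (8, 8))
        c_e = rng.uniform(0, 1, (8, 8))
        od1 = -np.log(render_he(c_n, c_e).rgb)
        od2 = -np.log(render_he(2 * c_n, c_e).rgb)
        hema_od = -np.log(render_he(c_n, np.zeros_like(c_e)).rgb)
        assert np.allclose(od2 - od1, hema_od, atol=1e-12)

    def test_monotone_darkening(self, rng):
        c_n = rng.uniform(0, 1, (8, 8))
        c_e = rng.uniform(0, 1, (8, 8))
        base = render_he(c_n, c_e).rgb
        more = render_he(c_n + 0.3, c_e).rgb
        assert (more <= base + 1e-15).all()

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            render_he(np.full((2, 2), -0.1), np.zeros((2, 2)))


class TestMisregistration:
    def test_zero_amplitude_is_identity(self, clean_phantom):
        moved, transform, lms = apply_misregistration(clean_phantom.he_true, 0.0, seed=1)
        assert transform.family == "identity"
        assert np.array_equal(moved.rgb, clean_phantom.he_true.rgb)
        assert np.array_equal(lms.ref, lms.mov)

    def test_landmark_displacement_bounded_by_amplitude(self, clean_phantom):
        amp = 4.0
        _, _, lms = apply_misregistration(clean_phantom.he_true, amp, seed=2)
        disp = np.linalg.norm(lms.ref - lms.mov, axis=1)
        assert disp.max() <= amp + 1e-9
        assert disp.max() > 0

    def test_true_warp_round_trip(self, small_phantom):
        """Warping the moving copy with the true transform recovers the
        original to interpolation tolerance on the interior."""
        s = small_phantom
        recovered = warp_image(s.he_moving, s.true_warp, s.he_true.shape)
        interior = np.s_[16:-16, 16:-16]
        mae = np.abs(recovered.rgb[interior] - s.he_true.rgb[interior]).mean()
        assert mae < 0.02


class TestScanStream:
    def test_jitter_free_positions_at_pixel_centers(self, clean_phantom):
        stream = emit_scan_stream(clean_phantom.contrast, jitter_px=0.0)
        h, w = clean_phantom.contrast.shape
        assert len(stream) == h * w
        pitch_um = clean_phantom.contrast.pixel_pitch_nm * 1e-3
        assert stream.x_um[0] == pytest.approx(0.5 * pitch_um)
        assert stream.y_um[0] == pytest.approx(0.5 * pitch_um)
        assert stream.x_um[1] == pytest.approx(1.5 * pitch_um)

    def test_jittered_records_bin_to_source_pixel(self, clean_phantom):
        """With sub-half-pixel jitter every record still bins home."""
        stream = emit_scan_stream(clean_phantom.contrast, jitter_px=0.4, seed=7)
        h, w = clean_phantom.contrast.shape
        pitch_um = clean_phantom.contrast.pixel_pitch_nm * 1e-3
        cols = np.floor(stream.x_um / pitch_um).astype(int)
        rows = np.floor(stream.y_um / pitch_um).astype(int)
        expected_cols = np.tile(np.arange(w), h)
        expected_rows = np.repeat(np.arange(h), w)
        assert np.array_equal(cols, expected_cols)
        assert np.array_equal(rows, expected_rows)
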