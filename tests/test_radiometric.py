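"""Flat field, reflectance conversion, SNR, and the alpha correction."""

import numpy as np
import pytest

import hsical as h
from hsical.spectral import WORKING_GRID


def cube_of(data, bandset, unit="counts", exposure_ms=10.0):
    return h.BandCube(np.asarray(data, dtype=float), bandset, unit=unit,
                      exposure_ms=exposure_ms)


class TestAverageDark:
    def test_constant_stack(self):
        dark = h.average_dark([np.full((4, 4), 7.0)] * 10, exposure_ms=5.0)
        np.testing.assert_array_equal(dark.mean_frame, 7.0)
        np.testing.assert_array_equal(dark.noise_sd, 0.0)

    def test_alternating_values(self):
        frames = [np.full((2, 2), 4.0), np.full((2, 2), 6.0)] * 3
        dark = h.average_dark(frames, exposure_ms=5.0)
        np.testing.assert_array_equal(dark.mean_frame, 5.0)

    def test_sampling_distribution(self, rng):
        frames = [rng.normal(10.0, 2.0, (8, 8)) for _ in range(500)]
        dark = h.average_dark(frames, exposure_ms=5.0)
        assert dark.mean_frame.mean() == pytest.approx(10.0, abs=0.3)
        assert dark.noise_sd.mean() == pytest.approx(2.0, abs=0.2)

    def test_single_frame_flagged(self):
        with pytest.warns(UserWarning):
            dark = h.average_dark([np.zeros((2, 2))], exposure_ms=1.0)
        assert not dark.sd_valid


class TestFlatField:
    def test_uniform_frame_gives_unit_gain(self, c44_bandset):
        cube = cube_of(np.full((16, 25, 25), 3.0), c44_bandset)
        gain = h.estimate_flat_field(cube, center_window_px=5)
        np.testing.assert_allclose(gain.gain, 1.0)
        # spec invariant: center-window mean of the gain is 1
        assert gain.gain[:, 12 - 5:12 + 6, 12 - 5:12 + 6].mean() == pytest.approx(
            1.0, abs=1e-6
        )

    def test_double_intensity_pixel_gets_half_gain(self, c44_bandset):
        data = np.full((16, 25, 25), 2.0)
        data[:, 0, 0] = 4.0
        gain = h.estimate_flat_field(cube_of(data, c44_bandset), center_window_px=5)
        np.testing.assert_allclose(gain.gain[:, 0, 0], 0.5)

    def test_vignetting_inverted_by_estimated_gain(self, c44_bandset):
        resp = h.make_sensor_responses(c44_bandset)
        illum = h.make_illumination("flat")
        acq = h.AcquisitionParams(
            exposure_ms=5.0, gain_counts=0.02, dark_offset_counts=0.0,
            vignetting_strength=0.3,
        )
        curve = h.SpectralCurve(WORKING_GRID, np.full_like(WORKING_GRID, 0.95))
        scene = h.SceneModel(np.zeros((100, 100), dtype=int), {0: curve})
        frame = h.render_mosaic_frame(scene, illum, resp, acq)
        cube = h.demosaic(frame)
        gain = h.estimate_flat_field(cube, center_window_px=5)
        flat = h.apply_flat_field(cube, gain)
        ratio = flat.data[:, 0, 0] / flat.data[:, 12, 12]
        np.testing.assert_allclose(ratio, 1.0, atol=1e-6)

    def test_window_exceeding_image_rejected(self, c44_bandset):
        cube = cube_of(np.ones((16, 8, 8)), c44_bandset)
        with pytest.raises(ValueError):
            h.estimate_flat_field(cube, center_window_px=10)

    def test_apply_identity_and_scaling(self, c44_bandset):
        cube = cube_of(np.full((16, 25, 25), 5.0), c44_bandset)
        unit_gain = h.FlatFieldGain(np.ones((16, 25, 25)), 5)
        np.testing.assert_array_equal(
            h.apply_flat_field(cube, unit_gain).data, cube.data
        )
        double = h.FlatFieldGain(np.full((16, 25, 25), 2.0), 5)
        np.testing.assert_array_equal(
            h.apply_flat_field(cube, double).data, 10.0
        )

    def test_band_mismatch_rejected(self, c44_bandset):
        cube = cube_of(np.ones((16, 25, 25)), c44_bandset)
        wrong = h.FlatFieldGain(np.ones((16, 10, 10)), 2)
        with pytest.raises(ValueError):
            h.apply_flat_field(cube, wrong)


def make_dark(value, shape=(4, 4), exposure_ms=10.0):
    return h.DarkReference(
        mean_frame=np.full(shape, float(value)),
        noise_sd=np.zeros(shape),
        exposure_ms=exposure_ms,
        n_frames=10,
    )


class TestToReflectance:
    def test_self_reference_gives_unity(self, c44_bandset):
        raw = cube_of(np.full((16, 4, 4), 900.0), c44_bandset, exposure_ms=10.0)
        white = h.WhiteReference(np.full((4, 4), 900.0), exposure_ms=10.0)
        res = h.to_reflectance(raw, make_dark(100), white, make_dark(100))
        np.testing.assert_allclose(res.data, 1.0)
        assert res.unit == "reflectance"

    def test_hand_computed_example(self, c44_bandset):
        # (600 - 100) / (1100 - 100) * 2 = 1.0
        raw = cube_of(np.full((16, 4, 4), 600.0), c44_bandset, exposure_ms=5.0)
        white = h.WhiteReference(np.full((4, 4), 1100.0), exposure_ms=10.0)
        res = h.to_reflectance(raw, make_dark(100, exposure_ms=5.0), white,
                               make_dark(100, exposure_ms=10.0))
        np.testing.assert_allclose(res.data, 1.0)

    def test_raw_equal_dark_gives_zero(self, c44_bandset):
        raw = cube_of(np.full((16, 4, 4), 100.0), c44_bandset)
        white = h.WhiteReference(np.full((4, 4), 1100.0), exposure_ms=10.0)
        res = h.to_reflectance(raw, make_dark(100), white, make_dark(100))
        np.testing.assert_allclose(res.data, 0.0)

    def test_exposure_ratio_invariance(self, c44_bandset):
        # halving the raw exposure halves the signal; Eq-level result unchanged
        signal = 800.0
        raw_full = cube_of(np.full((16, 4, 4), 100.0 + signal), c44_bandset,
                           exposure_ms=10.0)
        raw_half = cube_of(np.full((16, 4, 4), 100.0 + signal / 2), c44_bandset,
                           exposure_ms=5.0)
        white = h.WhiteReference(np.full((4, 4), 1100.0), exposure_ms=10.0)
        r1 = h.to_reflectance(raw_full, make_dark(100), white, make_dark(100))
        r2 = h.to_reflectance(raw_half, make_dark(100, exposure_ms=5.0), white,
                              make_dark(100))
        np.testing.assert_allclose(r1.data, r2.data, atol=1e-9)

    def test_nonpositive_white_masked(self, c44_bandset):
        raw = cube_of(np.full((16, 2, 2), 500.0), c44_bandset)
        wframe = np.full((2, 2), 1100.0)
        wframe[0, 0] = 50.0  # below its dark
        res = h.to_reflectance(raw, make_dark(100, (2, 2)),
                               h.WhiteReference(wframe, exposure_ms=10.0),
                               make_dark(100, (2, 2)))
        assert np.isnan(res.data[:, 0, 0]).all()
        assert np.isfinite(res.data[:, 1, 1]).all()

    def test_missing_exposure_rejected(self, c44_bandset):
        raw = h.BandCube(np.ones((16, 2, 2)), c44_bandset, unit="counts")
        white = h.WhiteReference(np.full((2, 2), 1100.0), exposure_ms=10.0)
        with pytest.raises(ValueError):
            h.to_reflectance(raw, make_dark(100, (2, 2)), white)

    def test_negative_values_kept_not_clipped(self, c44_bandset):
        raw = cube_of(np.full((16, 2, 2), 90.0), c44_bandset)  # below dark
        white = h.WhiteReference(np.full((2, 2), 1100.0), exposure_ms=10.0)
        res = h.to_reflectance(raw, make_dark(100, (2, 2)), white,
                               make_dark(100, (2, 2)))
        assert np.all(res.data < 0)


class TestSNR:
    def test_direct_formula(self):
        dark = h.DarkReference(np.zeros((8, 8)), np.full((8, 8), 2.0), 10.0, 100)
        assert h.compute_snr(100.0, dark)[0] == pytest.approx(50.0)
        assert h.compute_snr(0.0, dark)[0] == 0.0

    def test_zero_sigma_is_an_error(self):
        dark = h.DarkReference(np.zeros((8, 8)), np.zeros((8, 8)), 10.0, 100)
        with pytest.raises(ZeroDivisionError):
            h.compute_snr(100.0, dark)

    def test_led_nir_snr_below_visible(self):
        result = h.simulate_and_calibrate(
            "filter_wheel", "led", seed=2, read_noise_sd=2.0, n_dark=16
        )
        centers = result.final_cube.bandset.centers_nm
        snr = result.snr
        assert snr is not None
        nir = snr[centers >= 750].mean()
        vis = snr[(centers >= 500) & (centers <= 640)].mean()
        assert nir < vis


class TestFitAlpha:
    def attenuated(self, chart, factor, corrupt_nir=False):
        measured = {}
        for name in chart.tile_names:
            c = chart.reflectance[name]
            vals = c.values / factor
            if corrupt_nir:
                vals = np.where(c.wavelengths_nm > 850.0, vals * 10, vals)
            measured[name] = h.SpectralCurve(c.wavelengths_nm, vals)
        return measured

    def test_identity_fit(self, chart):
        sc = h.fit_alpha({n: chart.reflectance[n] for n in chart.tile_names}, chart)
        assert sc.alpha == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("factor", [2.01, 1.22, 1.07, 1.03])
    def test_injected_factor_recovered(self, chart, factor):
        sc = h.fit_alpha(self.attenuated(chart, factor), chart)
        assert sc.alpha == pytest.approx(factor, abs=1e-9)

    def test_nir_corruption_excluded_by_cutoff(self, chart):
        sc = h.fit_alpha(self.attenuated(chart, 1.22, corrupt_nir=True), chart,
                         lambda_max_nm=850.0)
        assert sc.alpha == pytest.approx(1.22, abs=1e-9)

    def test_scale_equivariance(self, chart, rng):
        measured = self.attenuated(chart, 1.5)
        sc1 = h.fit_alpha(measured, chart)
        k = 3.7
        scaled = {
            n: h.SpectralCurve(c.wavelengths_nm, c.values * k)
            for n, c in measured.items()
        }
        sc2 = h.fit_alpha(scaled, chart)
        assert sc2.alpha == pytest.approx(sc1.alpha / k, rel=1e-12)

    def test_no_usable_points_rejected(self, chart):
        with pytest.raises(ValueError):
            h.fit_alpha({}, chart)


class TestApplyAlphaAndValidation:
    def test_apply_alpha_scales(self, c44_bandset):
        cube = cube_of(np.full((16, 4, 4), 0.3), c44_bandset, unit="reflectance")
        sc = h.ScaleCorrection(alpha=2.0)
        np.testing.assert_allclose(h.apply_alpha(cube, sc).data, 0.6)
        one = h.ScaleCorrection(alpha=1.0)
        np.testing.assert_array_equal(h.apply_alpha(cube, one).data, cube.data)

    def test_alpha_requires_reflectance(self, c44_bandset):
        cube = cube_of(np.ones((16, 4, 4)), c44_bandset, unit="counts")
        with pytest.raises(ValueError):
            h.apply_alpha(cube, h.ScaleCorrection(alpha=2.0))

    def test_constant_offset_shows_up_as_mean_d(self, chart, dual_bandset):
        # cube holding chart tile spectra sampled at band centers, +0.05 offset
        centers = dual_bandset.centers_nm
        data = np.zeros((41, 4, 24))
        masks = {}
        for idx, name in enumerate(chart.tile_names):
            ref = chart.reflectance[name](centers)
            data[:, :, idx] = ref[:, None] + 0.05
            m = np.zeros((4, 24), dtype=bool)
            m[:, idx] = True
            masks[idx] = m
        cube = h.BandCube(data, dual_bandset, unit="reflectance")
        report = h.validate_against_chart(cube, chart, masks)
        for d in report.difference.values():
            np.testing.assert_allclose(d, 0.05, atol=1e-9)

    def test_round_trip_alpha_residual_near_zero(self, chart):
        # attenuate, fit, re-apply: residuals vanish at the fitted wavelengths
        measured = {
            n: h.SpectralCurve(
                chart.reflectance[n].wavelengths_nm,
                chart.reflectance[n].values / 2.01,
            )
            for n in chart.tile_names
        }
        sc = h.fit_alpha(measured, chart)
        for n in chart.tile_names:
            w = measured[n].wavelengths_nm
            sel = w <= 850.0
            d = sc.alpha * measured[n].values[sel] - chart.reflectance[n].values[sel]
            np.testing.assert_allclose(d, 0.0, atol=1e-9)
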