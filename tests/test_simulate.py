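"""Forward model: chart, illumination, responses, frame rendering."""

import numpy as np
import pytest

import hsical as h
from hsical.simulate import GRAY_LEVELS
from hsical.spectral import WORKING_GRID


class TestReferenceChart:
    def test_24_tiles_62_samples(self, chart):
        assert len(chart.tile_names) == 24
        for name in chart.tile_names:
            assert chart.reflectance[name].values.shape == (62,)

    def test_gray_tiles_flat(self, chart):
        grays = [n for n in chart.tile_names if n.startswith("gray")]
        assert len(grays) == 6
        for name, level in zip(grays, GRAY_LEVELS):
            vals = chart.reflectance[name].values
            assert vals.std() == pytest.approx(0.0, abs=1e-12)
            assert vals[0] == pytest.approx(level)

    def test_seeding_contract(self):
        a, b = h.make_reference_chart(1), h.make_reference_chart(2)
        for name in a.tile_names:
            if name.startswith("gray"):
                np.testing.assert_array_equal(
                    a.reflectance[name].values, b.reflectance[name].values
                )
        colored = [n for n in a.tile_names if n.startswith("color")]
        assert any(
            not np.array_equal(a.reflectance[n].values, b.reflectance[n].values)
            for n in colored
        )

    def test_sd_envelope_grows_into_nir(self, chart):
        name = chart.tile_names[0]
        sd = chart.sd[name]
        vis = sd[chart.grid <= 500].mean()
        nir = sd[chart.grid >= 900].mean()
        assert nir > 10 * vis
        assert sd.min() >= 0.0


class TestIllumination:
    def test_led_nir_below_10pct_of_peak(self):
        led = h.make_illumination("led")
        assert led.curve(900.0) < 0.1 * led.curve(460.0)

    def test_xenon_nonzero_400_to_850(self):
        xe = h.make_illumination("xenon")
        grid = np.arange(400.0, 851.0, 1.0)
        assert np.all(xe.curve(grid) > 0)

    def test_flat_is_unit(self):
        flat = h.make_illumination("flat")
        np.testing.assert_array_equal(flat.curve.values, 1.0)

    def test_sources_clip_below_400nm(self):
        for kind in ("xenon", "led"):
            curve = h.make_illumination(kind).curve
            assert np.all(curve.values[curve.wavelengths_nm < 400] == 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            h.make_illumination("halogen")


def count_local_maxima(vals):
    interior = (vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:])
    significant = vals[1:-1] > 0.01 * vals.max()
    return int(np.sum(interior & significant))


class TestSensorResponses:
    def test_cam4x4_16_unimodal_curves(self, c44_bandset):
        resp = h.make_sensor_responses(c44_bandset)
        assert len(resp.responses) == 16
        for r in resp.responses:
            assert count_local_maxima(r.values) == 1

    def test_secondary_peak_gives_two_maxima(self, c55_bandset):
        resp = h.make_sensor_responses(c55_bandset, [(13, 732.0, 0.3)])
        assert count_local_maxima(resp.responses[13].values) == 2

    def test_cam5x5_peak_heights_low(self, c55_bandset):
        resp = h.make_sensor_responses(c55_bandset)
        assert max(r.values.max() for r in resp.responses) <= 0.12

    def test_secondary_height_must_be_below_primary(self, c55_bandset):
        with pytest.raises(ValueError):
            h.make_sensor_responses(c55_bandset, [(13, 732.0, 1.5)])


def flat_scene(height, width, reflectance=1.0):
    curve = h.SpectralCurve(WORKING_GRID, np.full_like(WORKING_GRID, reflectance))
    return h.SceneModel(np.zeros((height, width), dtype=int), {0: curve})


NOISELESS = dict(read_noise_sd_counts=0.0, shot_noise=False)


class TestRenderMosaic:
    def test_zero_illumination_gives_dark_offset(self, c44_bandset):
        resp = h.make_sensor_responses(c44_bandset)
        dark_illum = h.IlluminationSpectrum(
            "flat", h.SpectralCurve(WORKING_GRID, np.zeros_like(WORKING_GRID))
        )
        acq = h.AcquisitionParams(exposure_ms=10.0, dark_offset_counts=42.0, **NOISELESS)
        frame = h.render_mosaic_frame(flat_scene(8, 8), dark_illum, resp, acq)
        np.testing.assert_array_equal(frame.pixels, 42.0)

    def test_signal_linear_in_exposure(self, c44_bandset):
        resp = h.make_sensor_responses(c44_bandset)
        illum = h.make_illumination("flat")
        acq1 = h.AcquisitionParams(exposure_ms=5.0, gain_counts=0.01, **NOISELESS)
        acq2 = h.AcquisitionParams(exposure_ms=10.0, gain_counts=0.01, **NOISELESS)
        f1 = h.render_mosaic_frame(flat_scene(8, 8), illum, resp, acq1)
        f2 = h.render_mosaic_frame(flat_scene(8, 8), illum, resp, acq2)
        np.testing.assert_allclose(
            f2.pixels - acq2.dark_offset_counts,
            2 * (f1.pixels - acq1.dark_offset_counts),
            rtol=1e-12,
        )

    def test_counts_match_brute_force_quadrature(self, c44_bandset):
        resp = h.make_sensor_responses(c44_bandset)
        illum = h.make_illumination("flat")
        acq = h.AcquisitionParams(
            exposure_ms=7.0, gain_counts=0.02, dark_offset_counts=0.0, **NOISELESS
        )
        frame = h.render_mosaic_frame(flat_scene(4, 4), illum, resp, acq)
        # independent Riemann sum, explicit loop
        for band in c44_bandset.bands:
            r, c = divmod(band.sensor_index, 4)
            total = 0.0
            grid = resp.grid
            vals = resp.responses[band.sorted_index].values
            for i in range(len(grid)):
                dl = (
                    grid[min(i + 1, len(grid) - 1)] - grid[max(i - 1, 0)]
                ) / (2 if 0 < i < len(grid) - 1 else 1)
                total += vals[i] * 1.0 * 1.0 * dl
            expected = acq.exposure_ms * acq.gain_counts * total
            assert frame.pixels[r, c] == pytest.approx(expected, rel=1e-3)

    def test_dimension_mismatch_rejected(self, c55_bandset):
        resp = h.make_sensor_responses(c55_bandset)
        acq = h.AcquisitionParams(exposure_ms=1.0, **NOISELESS)
        with pytest.raises(ValueError):
            h.render_mosaic_frame(flat_scene(8, 8), h.make_illumination("flat"), resp, acq)

    def test_same_seed_bit_identical(self, c44_bandset):
        resp = h.make_sensor_responses(c44_bandset)
        illum = h.make_illumination("xenon")
        acq = h.AcquisitionParams(
            exposure_ms=5.0, gain_counts=0.01, read_noise_sd_counts=2.0,
            shot_noise=True, seed=99,
        )
        f1 = h.render_mosaic_frame(flat_scene(8, 8), illum, resp, acq)
        f2 = h.render_mosaic_frame(flat_scene(8, 8), illum, resp, acq)
        np.testing.assert_array_equal(f1.pixels, f2.pixels)

    def test_vignetting_darkens_corners_only(self, c44_bandset):
        resp = h.make_sensor_responses(c44_bandset)
        illum = h.make_illumination("flat")
        base = h.AcquisitionParams(exposure_ms=5.0, gain_counts=0.01,
                                   dark_offset_counts=0.0, **NOISELESS)
        vig = h.AcquisitionParams(exposure_ms=5.0, gain_counts=0.01,
                                  dark_offset_counts=0.0,
                                  vignetting_strength=0.4, **NOISELESS)
        f0 = h.render_mosaic_frame(flat_scene(16, 16), illum, resp, base).pixels
        f1 = h.render_mosaic_frame(flat_scene(16, 16), illum, resp, vig).pixels
        assert f1[0, 0] == pytest.approx(0.6 * f0[0, 0], rel=1e-9)
        center = f1[7:9, 7:9] / f0[7:9, 7:9]
        assert center.min() > 0.98


class TestRenderFilterWheel:
    def test_19_frames(self, fw_bandset):
        acq = h.AcquisitionParams(exposure_ms=5.0, gain_counts=0.05, **NOISELESS)
        stack = h.render_filterwheel_stack(flat_scene(8, 8), fw_bandset, acq)
        assert stack.frames.shape[0] == 19

    def test_linearity_in_reflectance(self, fw_bandset):
        acq = h.AcquisitionParams(exposure_ms=5.0, gain_counts=0.05,
                                  dark_offset_counts=50.0, **NOISELESS)
        s_half = h.render_filterwheel_stack(flat_scene(8, 8, 0.5), fw_bandset, acq)
        s_full = h.render_filterwheel_stack(flat_scene(8, 8, 1.0), fw_bandset, acq)
        ratio = (s_half.frames - 50.0).mean(axis=(1, 2)) / (
            s_full.frames - 50.0
        ).mean(axis=(1, 2))
        np.testing.assert_allclose(ratio, 0.5, rtol=1e-9)

    def test_led_starves_the_850nm_band(self, fw_bandset):
        acq = h.AcquisitionParams(exposure_ms=5.0, gain_counts=0.05,
                                  dark_offset_counts=10.0, **NOISELESS)
        stack = h.render_filterwheel_stack(
            flat_scene(8, 8), fw_bandset, acq, illumination=h.make_illumination("led")
        )
        sig = stack.frames.mean(axis=(1, 2)) - 10.0
        centers = fw_bandset.centers_nm
        b850 = sig[np.where(centers == 850)[0][0]]
        b540 = sig[np.where(centers == 540)[0][0]]
        assert b850 < 0.05 * b540

    def test_wrong_bandset_rejected(self, c44_bandset):
        acq = h.AcquisitionParams(exposure_ms=5.0, **NOISELESS)
        with pytest.raises(ValueError):
            h.render_filterwheel_stack(flat_scene(8, 8), c44_bandset, acq)


class TestReferenceFrames:
    def test_dark_series_sd_matches_configured_noise(self, c44_bandset):
        resp = h.make_sensor_responses(c44_bandset)
        acq = h.AcquisitionParams(
            exposure_ms=5.0, gain_counts=0.01, read_noise_sd_counts=2.0, seed=3
        )
        darks, _ = h.render_reference_frames(
            acq, h.make_illumination("flat"), resp, n_dark=100, shape=(16, 16)
        )
        stack = np.stack(darks)
        assert stack.std(axis=0, ddof=1).mean() == pytest.approx(2.0, rel=0.1)

    def test_white_without_light_equals_dark(self, c44_bandset):
        resp = h.make_sensor_responses(c44_bandset)
        off = h.IlluminationSpectrum(
            "flat", h.SpectralCurve(WORKING_GRID, np.zeros_like(WORKING_GRID))
        )
        acq = h.AcquisitionParams(exposure_ms=5.0, dark_offset_counts=77.0, **NOISELESS)
        darks, white = h.render_reference_frames(acq, off, resp, n_dark=2, shape=(8, 8))
        assert white.pixels.mean() == pytest.approx(np.stack(darks).mean())

    def test_white_board_reflectance_is_095(self, c44_bandset):
        resp = h.make_sensor_responses(c44_bandset)
        illum = h.make_illumination("flat")
        acq = h.AcquisitionParams(exposure_ms=5.0, gain_counts=0.01,
                                  dark_offset_counts=0.0, **NOISELESS)
        _, white = h.render_reference_frames(acq, illum, resp, n_dark=1, shape=(8, 8))
        unit = h.render_mosaic_frame(flat_scene(8, 8, 1.0), illum, resp, acq)
        np.testing.assert_allclose(white.pixels, 0.95 * unit.pixels, rtol=1e-12)
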