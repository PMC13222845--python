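"""Cube I/O, calibration and spectral preprocessing."""

import numpy as np
import pytest

from kernelpheno.cube_io import (SpectralCube, calibrate_reflectance, crop_bands,
                                 read_envi_cube, render_rgb,
                                 smooth_savitzky_golay, write_envi_cube)


def small_cube(rows=2, cols=2, bands=3, seed=0):
    rng = np.random.default_rng(seed)
    wl = np.linspace(500, 700, bands)
    return SpectralCube(rng.uniform(0.1, 0.9, (rows, cols, bands)), wl)


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_round_trip_identity(self, tmp_path, interleave):
        cube = small_cube(3, 4, 5)
        hdr = tmp_path / f"cube_{interleave}.hdr"
        write_envi_cube(cube, hdr, interleave=interleave)
        back = read_envi_cube(hdr)
        np.testing.assert_array_equal(back.reflectance,
                                      cube.reflectance.astype(np.float32))
        np.testing.assert_allclose(back.wavelengths, cube.wavelengths, atol=1e-4)

    def test_interleaves_agree(self, tmp_path):
        cube = small_cube(2, 2, 3)
        cubes = []
        for il in ("bip", "bsq", "bil"):
            hdr = tmp_path / f"c_{il}.hdr"
            write_envi_cube(cube, hdr, interleave=il)
            cubes.append(read_envi_cube(hdr).reflectance)
        np.testing.assert_array_equal(cubes[0], cubes[1])
        np.testing.assert_array_equal(cubes[0], cubes[2])

    def test_wavelength_count_mismatch_is_hard_error(self, tmp_path):
        cube = small_cube(2, 2, 4)
        hdr = tmp_path / "bad.hdr"
        write_envi_cube(cube, hdr)
        text = hdr.read_text().replace("bands = 4", "bands = 4")
        # drop one wavelength from the header list
        lines = text.splitlines()
        wl_line = [ln for ln in lines if ln.startswith("wavelength =")][0]
        broken = wl_line.rsplit(",", 1)[0] + " }"
        hdr.write_text(text.replace(wl_line, broken))
        with pytest.raises(ValueError, match="wavelengths"):
            read_envi_cube(hdr)

    def test_missing_wavelength_key_is_hard_error(self, tmp_path):
        cube = small_cube()
        hdr = tmp_path / "nowl.hdr"
        write_envi_cube(cube, hdr)
        lines = [ln for ln in hdr.read_text().splitlines()
                 if not ln.startswith("wavelength =")]
        hdr.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="wavelength"):
            read_envi_cube(hdr)

    def test_uint16_payload(self, tmp_path):
        data = np.arange(24, dtype=np.uint16).reshape(2, 3, 4)
        hdr = tmp_path / "u16.hdr"
        hdr.write_text(
            "ENVI\nsamples = 3\nlines = 2\nbands = 4\nheader offset = 0\n"
            "data type = 12\ninterleave = bip\nbyte order = 0\n"
            "wavelength = { 400, 500, 600, 700 }\n")
        data.tofile(tmp_path / "u16.dat")
        cube = read_envi_cube(hdr)
        np.testing.assert_array_equal(cube.reflectance, data)


class TestCalibration:
    def test_raw_equals_white_gives_ones(self):
        raw = small_cube(seed=1)
        out = calibrate_reflectance(raw, raw)
        np.testing.assert_allclose(out.reflectance, 1.0)

    def test_raw_equals_dark_gives_zeros(self):
        raw = small_cube(seed=2)
        white = SpectralCube(raw.reflectance + 0.5, raw.wavelengths)
        out = calibrate_reflectance(white, white, dark=raw)
        # raw==dark case: calibrate(raw=dark_cube)
        out = calibrate_reflectance(raw, white, dark=raw)
        np.testing.assert_allclose(out.reflectance, 0.0)

    def test_midpoint_gives_half(self):
        dark = small_cube(seed=3)
        white = SpectralCube(dark.reflectance + 1.0, dark.wavelengths)
        mid = SpectralCube(0.5 * (white.reflectance + dark.reflectance),
                           dark.wavelengths)
        out = calibrate_reflectance(mid, white, dark=dark)
        np.testing.assert_allclose(out.reflectance, 0.5, atol=1e-12)

    def test_single_spectrum_white_broadcasts(self):
        raw = small_cube(4, 4, 3, seed=4)
        spec = np.full((1, 1, 3), 2.0)
        white = SpectralCube(spec, raw.wavelengths)
        out = calibrate_reflectance(raw, white)
        np.testing.assert_allclose(out.reflectance, raw.reflectance / 2.0)

    def test_zero_denominator_flags_nonfinite_not_error(self):
        raw = small_cube(seed=5)
        white = SpectralCube(np.zeros_like(raw.reflectance), raw.wavelengths)
        out = calibrate_reflectance(raw, white)
        assert not np.isfinite(out.reflectance).all()


class TestCropBands:
    WL = np.array([400.0, 425.0, 500.0, 974.0, 1000.0])

    def make(self):
        return SpectralCube(np.ones((1, 1, 5)) * np.arange(5), self.WL)

    def test_inclusive_boundaries(self):
        out = crop_bands(self.make(), 425, 974)
        np.testing.assert_array_equal(out.wavelengths, [425, 500, 974])

    def test_full_range_is_identity(self):
        out = crop_bands(self.make(), 0, np.inf)
        np.testing.assert_array_equal(out.wavelengths, self.WL)

    def test_upper_tail(self):
        out = crop_bands(self.make(), 975, 1000)
        np.testing.assert_array_equal(out.wavelengths, [1000])

    def test_idempotent(self):
        once = crop_bands(self.make(), 425, 974)
        twice = crop_bands(once, 425, 974)
        np.testing.assert_array_equal(once.reflectance, twice.reflectance)

    def test_empty_result_is_hard_error(self):
        with pytest.raises(ValueError):
            crop_bands(self.make(), 1500, 1600)


class TestSavitzkyGolay:
    def test_constant_spectrum_unchanged(self):
        cube = SpectralCube(np.full((2, 2, 21), 0.4), np.arange(21.0))
        out = smooth_savitzky_golay(cube, 11, 2)
        np.testing.assert_allclose(out.reflectance, 0.4, atol=1e-10)

    def test_quadratic_reproduced(self):
        x = np.arange(25.0)
        spec = 0.3 + 0.02 * x - 0.001 * x**2
        cube = SpectralCube(np.tile(spec, (2, 2, 1)), x)
        out = smooth_savitzky_golay(cube, 11, 2)
        np.testing.assert_allclose(out.reflectance, cube.reflectance, atol=1e-8)

    def test_spike_attenuation_matches_projection_oracle(self):
        # central smoothing weight of the (11, 2) filter computed directly
        # from the local least-squares projection it is defined to be
        offsets = np.arange(-5, 6, dtype=float)
        A = np.vander(offsets, 3, increasing=True)
        H = A @ np.linalg.inv(A.T @ A) @ A.T
        center_weight = H[5, 5]
        spec = np.zeros(31)
        spec[15] = 1.0
        cube = SpectralCube(np.tile(spec, (1, 1, 1)), np.arange(31.0))
        out = smooth_savitzky_golay(cube, 11, 2)
        peak = out.reflectance[0, 0, 15]
        assert peak == pytest.approx(center_weight, abs=1e-10)
        assert peak < 0.5

    def test_linearity(self, rng):
        wl = np.arange(31.0)
        x = SpectralCube(rng.normal(size=(3, 3, 31)), wl)
        y = SpectralCube(rng.normal(size=(3, 3, 31)), wl)
        a, b = 1.7, -0.4
        combo = SpectralCube(a * x.reflectance + b * y.reflectance, wl)
        lhs = smooth_savitzky_golay(combo, 11, 2).reflectance
        rhs = (a * smooth_savitzky_golay(x, 11, 2).reflectance
               + b * smooth_savitzky_golay(y, 11, 2).reflectance)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    @pytest.mark.parametrize("window,order,nbands", [(10, 2, 31), (5, 7, 31), (31, 2, 31)])
    def test_invalid_filter_config_is_error(self, window, order, nbands):
        cube = SpectralCube(np.ones((1, 1, nbands)), np.arange(float(nbands)))
        with pytest.raises(ValueError):
            smooth_savitzky_golay(cube, window, order)


class TestRenderRgb:
    def test_uniform_cube_gives_uniform_image(self):
        wl = np.linspace(425, 974, 20)
        cube = SpectralCube(np.full((4, 4, 20), 0.5), wl)
        img = render_rgb(cube)
        assert len(np.unique(img.pixels)) == 1

    def test_nearest_band_lookup(self):
        wl = np.array([430.0, 470.0, 545.0, 655.0, 900.0])
        cube = SpectralCube(np.random.default_rng(0).uniform(size=(2, 2, 5)), wl)
        img = render_rgb(cube, bands_nm=(640, 550, 460))
        assert img.band_indices == (3, 2, 1)

    def test_nearest_tie_prefers_lower_wavelength(self):
        wl = np.array([500.0, 600.0, 700.0])
        cube = SpectralCube(np.ones((1, 1, 3)), wl)
        assert cube.nearest_band(550.0) == 0

    def test_bright_pixel_maps_to_255(self):
        wl = np.linspace(425, 974, 6)
        data = np.full((3, 3, 6), 0.1)
        data[1, 1, :] = 0.9
        img = render_rgb(SpectralCube(data, wl))
        assert tuple(img.pixels[1, 1]) == (255, 255, 255)

    def test_out_of_range_request_is_error(self):
        wl = np.linspace(500, 600, 5)
        cube = SpectralCube(np.ones((1, 1, 5)), wl)
        with pytest.raises(ValueError):
            render_rgb(cube, bands_nm=(640, 550, 460))


class TestSpectralCubeInvariants:
    def test_band_wavelength_count_must_match(self):
        with pytest.raises(ValueError):
            SpectralCube(np.ones((2, 2, 3)), np.array([500.0, 600.0]))

    def test_wavelengths_must_increase(self):
        with pytest.raises(ValueError):
            SpectralCube(np.ones((1, 1, 3)), np.array([500.0, 500.0, 600.0]))
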