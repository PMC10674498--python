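"""Propagation, lens transforms, NA masking and the observation simulator."""

import numpy as np
import pytest

from sadhm import (ComplexField, OpticalConfig, ZernikeCoefficients,
                   apply_na_mask, illumination_wavevector, lens_fourier,
                   propagate, simulate_observation)
from sadhm.wave_optics import aperture_field, cfft2, image_through_system


def gaussian_field(n=128, width=12.0, pitch=1.0, wavelength=0.532):
    r2 = ((np.arange(n) - n / 2)[:, None] ** 2 + (np.arange(n) - n / 2)[None, :] ** 2)
    return ComplexField(np.exp(-r2 / (2 * width**2)), pitch, wavelength)


class TestWavevector:
    def test_on_axis(self):
        wv = illumination_wavevector(1.5, 0.0, 0.0, 6.6, 0.532)
        assert wv.kx == wv.ky == 0.0
        assert wv.kz == pytest.approx(2 * np.pi / 0.532e-3)

    def test_magnitude_is_wavenumber(self):
        wv = illumination_wavevector(2.0, 0.8, -0.3, 6.6, 0.532)
        assert wv.magnitude == pytest.approx(2 * np.pi / 0.532e-3, rel=1e-12)

    def test_invalid_working_distance(self):
        with pytest.raises(ValueError):
            illumination_wavevector(1.5, 0.0, 0.0, -1.0, 0.532)


class TestPropagate:
    def test_zero_distance_identity(self):
        f = gaussian_field()
        assert propagate(f, 0.0) is f

    def test_energy_conserved(self):
        # distance small enough that the anti-aliasing band limit does not
        # clip the Gaussian's spectrum on this grid
        f = gaussian_field()
        assert propagate(f, 0.2).energy == pytest.approx(f.energy, rel=1e-9)

    def test_plane_wave_phase_advance(self):
        """An on-axis plane wave picks up exp(j 2 pi d / lambda)."""
        f = ComplexField(np.ones((64, 64), complex), 1.0, 0.532)
        d_mm = 0.0005  # 0.5 um, keeps 2 pi d / lambda modest
        out = propagate(f, d_mm)
        expected = np.exp(2j * np.pi * d_mm * 1000 / 0.532)
        np.testing.assert_allclose(out.values, expected, rtol=1e-9)

    def test_back_propagation_inverts(self):
        f = gaussian_field()
        rt = propagate(propagate(f, 0.2), -0.2)
        rms = np.sqrt(np.mean(np.abs(rt.values - f.values) ** 2))
        assert rms < 1e-10 * np.abs(f.values).max()


class TestLensFourier:
    def test_uniform_aperture_gives_centered_peak(self, tiny_config):
        f = aperture_field(ZernikeCoefficients.zeros(), tiny_config)
        out = lens_fourier(f, tiny_config.f1)
        n = tiny_config.n_pixels
        assert np.unravel_index(np.abs(out.values).argmax(), (n, n)) == (n // 2, n // 2)
        # output-plane sampling lambda f / (N pitch)
        assert out.pixel_pitch == pytest.approx(
            0.532 * 10e3 / (tiny_config.n_pixels * 1.0))

    def test_double_transform_is_parity_flip(self, rng):
        values = rng.normal(size=(64, 64))
        f = ComplexField(values, 1.0, 0.532)
        twice = lens_fourier(lens_fourier(f, 10.0), 10.0).values
        flipped = np.roll(values[::-1, ::-1], (1, 1), axis=(0, 1))  # even-grid parity
        np.testing.assert_allclose(twice, flipped, atol=1e-10)

    def test_tilt_displaces_peak(self, tiny_config):
        c = ZernikeCoefficients.zeros().replace(c2=18.0)
        out = lens_fourier(aperture_field(c, tiny_config), tiny_config.f1)
        n = tiny_config.n_pixels
        peak = np.unravel_index(np.abs(out.values).argmax(), (n, n))
        bins = round(18.0 * n / (2 * np.pi * tiny_config.aperture_radius_px))
        assert peak == (n // 2, n // 2 + bins)


class TestNAMask:
    def test_mask_na_values(self):
        cfg = OpticalConfig()
        assert cfg.mask_na == pytest.approx(0.0266)
        assert cfg.grid_na == pytest.approx(0.266)

    def test_energy_never_increases_and_monotone(self, rng):
        f = ComplexField(rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64)),
                         1.0, 0.532)
        energies = [apply_na_mask(f, d).energy for d in (8, 16, 32, 64)]
        assert all(a <= b + 1e-12 for a, b in zip(energies, energies[1:]))
        assert energies[-1] <= f.energy + 1e-12

    def test_oversize_mask_rejected(self):
        f = gaussian_field(n=32)
        with pytest.raises(ValueError):
            apply_na_mask(f, 33)


class TestSimulateObservation:
    def test_bright_field_centered_blob(self, tiny_config):
        fourier_i, focal_i, defocus_i, cam = simulate_observation(
            ZernikeCoefficients.zeros(), tiny_config)
        n = tiny_config.n_pixels
        assert np.unravel_index(fourier_i.argmax(), fourier_i.shape) == (n // 2, n // 2)
        # energy: the mask only removes energy
        aperture_energy = aperture_field(ZernikeCoefficients.zeros(), tiny_config).energy
        assert cam.energy <= aperture_energy + 1e-9

    def test_dark_field_carrier_outside_mask(self, tiny_config):
        cfg = tiny_config
        c1, c2 = cfg.tilt_for_carrier_bins(3 * cfg.mask_radius_bins, 0.0)
        coeffs = ZernikeCoefficients.zeros().replace(c1=c1, c2=c2)
        assert cfg.is_dark_field(coeffs)
        fourier_i, *_ = simulate_observation(coeffs, cfg)
        n, r = cfg.n_pixels, cfg.mask_radius_bins
        # carrier peak is absent: masked Fourier energy far below the
        # bright-field case, and the peak no longer sits at the carrier
        bright_fourier, *_ = simulate_observation(ZernikeCoefficients.zeros(), cfg)
        assert fourier_i.sum() < 0.1 * bright_fourier.sum()

    def test_imaging_operator_is_linear(self, tiny_config, rng):
        cfg = tiny_config
        n = cfg.n_pixels
        a = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        b = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        fa = ComplexField(a, cfg.pixel_pitch, cfg.wavelength)
        fb = ComplexField(b, cfg.pixel_pitch, cfg.wavelength)
        fab = ComplexField(a + 2j * b, cfg.pixel_pitch, cfg.wavelength)
        lhs = image_through_system(fab, cfg).values
        rhs = (image_through_system(fa, cfg).values
               + 2j * image_through_system(fb, cfg).values)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_deterministic(self, tiny_config):
        c = ZernikeCoefficients(np.linspace(-1, 1, 10))
        out1 = simulate_observation(c, tiny_config)
        out2 = simulate_observation(c, tiny_config)
        for a, b in zip(out1[:3], out2[:3]):
            np.testing.assert_array_equal(a, b)


def test_config_validation_and_io(tmp_path):
    with pytest.raises(ValueError):
        OpticalConfig(fourier_mask_diameter_px=4000)
    with pytest.raises(ValueError):
        OpticalConfig(wavelength=-1)
    cfg = OpticalConfig.scaled()
    assert cfg.n_pixels == 560 and cfg.fourier_mask_diameter_px == 56
    assert cfg.mask_na == pytest.approx(0.0266)  # dimensionless ratios preserved
    for name in ("cfg.yaml", "cfg.json"):
        path = tmp_path / name
        cfg.to_file(path)
        assert OpticalConfig.from_file(path) == cfg
    with pytest.raises(ValueError):
        cfg.validate_tilt_range(1200.0)  # aliases at the scaled aperture
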