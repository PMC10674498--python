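"""Compensation, Fourier-domain synthesis, piston matching, full pipeline."""

import dataclasses

import numpy as np
import pytest

from sadhm import (TileOverlapError, ZernikeCoefficients, compensate,
                   match_piston, measure_illumination, reconstruct, synthesize)
from sadhm.sa_reconstruction import IlluminationRecord
from sadhm.wave_optics import ComplexField, aperture_field
from sadhm.zernike import aperture_mask


def grid_illuminations(cfg, spacing_bins, half=1, rng=None, aberration_scale=0.0):
    """Coefficient vectors whose carriers tile a (2*half+1)^2 Fourier grid."""
    ills = []
    for fy in range(-half, half + 1):
        for fx in range(-half, half + 1):
            c1, c2 = cfg.tilt_for_carrier_bins(fx * spacing_bins, fy * spacing_bins)
            c = np.zeros(10)
            c[1], c[2] = c1, c2
            if rng is not None:
                c[0] = rng.uniform(-np.pi, np.pi)
                if aberration_scale:
                    c[3:] = rng.uniform(-aberration_scale, aberration_scale, 7)
            ills.append(ZernikeCoefficients(c))
    return ills


def checkerboard(n, rng):
    return (rng.random((n, n)) > 0.5).astype(float)


class TestCompensate:
    def test_zero_coefficients_identity(self, tiny_config, rng):
        n = tiny_config.n_pixels
        rec = IlluminationRecord(0, (0.0, 0.0),
                                 ComplexField(rng.normal(size=(n, n)), 1.0, 0.532))
        out = compensate(rec, ZernikeCoefficients.zeros(), tiny_config)
        np.testing.assert_array_equal(out.field.values, rec.field.values)

    def test_exact_compensation_removes_high_orders(self, tiny_config):
        """Compensating a simulated aberrated field with the true coefficients
        leaves only piston + carrier: residual order-3..9 phase < 1e-6 rad."""
        cfg = tiny_config
        c = ZernikeCoefficients(np.array([0.4, 3.0, -2.0, 1.5, -2.5, 0.8, 1.0, -0.7, 0.9, -1.2]))
        field = aperture_field(c, cfg)
        rec = IlluminationRecord(0, cfg.carrier_bins(c), field, true_coeffs=c)
        out = compensate(rec, c, cfg)
        carrier_only = c.replace(**{f"c{n}": 0.0 for n in range(3, 10)})
        expected = aperture_field(carrier_only, cfg)
        mask = aperture_mask(cfg.grid) > 0
        residual = np.angle(out.field.values[mask] * np.conj(expected.values[mask]))
        assert np.abs(residual).max() < 1e-6

    def test_involution(self, tiny_config, rng):
        n = tiny_config.n_pixels
        rec = IlluminationRecord(0, (0.0, 0.0),
                                 ComplexField(rng.normal(size=(n, n))
                                              + 1j * rng.normal(size=(n, n)), 1.0, 0.532))
        c = ZernikeCoefficients(rng.normal(size=10))
        out = compensate(compensate(rec, c, tiny_config), -c, tiny_config)
        np.testing.assert_allclose(out.field.values, rec.field.values, atol=1e-12)


class TestSynthesize:
    def test_single_on_axis_identity(self, tiny_config, rng):
        sample = checkerboard(tiny_config.n_pixels, rng)
        rec = measure_illumination(sample, ZernikeCoefficients.zeros(), tiny_config)
        syn = synthesize([rec], tiny_config, match_pistons=False)
        np.testing.assert_allclose(syn.field.values, rec.field.values, atol=1e-12)

    def test_duplicate_records_average_not_double(self, tiny_config, rng):
        sample = checkerboard(tiny_config.n_pixels, rng)
        rec = measure_illumination(sample, ZernikeCoefficients.zeros(), tiny_config)
        rec2 = dataclasses.replace(rec, index=1)
        one = synthesize([rec], tiny_config, match_pistons=False)
        two = synthesize([rec, rec2], tiny_config, match_pistons=False)
        np.testing.assert_allclose(two.field.values, one.field.values, atol=1e-12)
        assert two.weight.max() == 2

    def test_spectral_support_is_union_of_shifted_discs(self, small_config, rng):
        cfg = small_config
        ills = grid_illuminations(cfg, spacing_bins=20)
        sample = checkerboard(cfg.n_pixels, rng)
        recs = [measure_illumination(sample, c, cfg, index=i)
                for i, c in enumerate(ills)]
        syn = synthesize(recs, cfg, match_pistons=False)
        n, r = cfg.n_pixels, cfg.mask_radius_bins
        expected = np.zeros((n, n), dtype=bool)
        cols = np.arange(n)[None, :]
        rows = np.arange(n)[:, None]
        for c in ills:
            fx, fy = cfg.carrier_bins(c)
            # tile lands at -carrier; fy counts upward (rows decrease)
            cx, cy = n // 2 - round(fx), n // 2 + round(fy)
            expected |= (cols - cx) ** 2 + (rows - cy) ** 2 <= r**2
        np.testing.assert_array_equal(syn.weight > 0, expected)

    def test_empty_input_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            synthesize([], tiny_config)

    def test_disjoint_tiles_superpose_independently(self, small_config, rng):
        """With disjoint spectral supports, adding more tiles does not change
        the synthesized spectrum on an existing tile's support."""
        cfg = small_config
        sample = checkerboard(cfg.n_pixels, rng)
        far = 3 * cfg.mask_radius_bins  # > 2r: no overlap
        ills = []
        for k in (0, 1, 2):
            c1, c2 = cfg.tilt_for_carrier_bins(k * far, 0.0)
            ills.append(ZernikeCoefficients.zeros().replace(c1=c1, c2=c2))
        recs = [measure_illumination(sample, c, cfg, index=i)
                for i, c in enumerate(ills)]
        only_a = synthesize(recs[:1], cfg, match_pistons=False)
        both = synthesize(recs, cfg, match_pistons=False)
        support_a = only_a.weight > 0
        assert not np.any((both.weight > 1)[support_a])
        np.testing.assert_allclose(both.spectrum[support_a],
                                   only_a.spectrum[support_a], atol=1e-12)


class TestPistonMatching:
    @staticmethod
    def _records(cfg, rng, spacing=10):
        sample = checkerboard(cfg.n_pixels, rng)
        ills = grid_illuminations(cfg, spacing_bins=spacing)
        return [measure_illumination(sample, c, cfg, index=i)
                for i, c in enumerate(ills)]

    def test_consistent_tiles_give_zero_offsets(self, small_config, rng):
        recs = self._records(small_config, rng)
        offsets = match_piston(recs, small_config)
        assert max(abs(v) for v in offsets.values()) < 1e-9

    def test_recovers_injected_pistons(self, small_config, rng):
        """Injected per-tile piston errors are recovered up to one global
        constant, to < 1e-6 rad."""
        recs = self._records(small_config, rng)
        deltas = rng.uniform(-np.pi, np.pi, len(recs))
        corrupted = [
            dataclasses.replace(r, field=r.field.with_values(
                r.field.values * np.exp(1j * d)))
            for r, d in zip(recs, deltas)
        ]
        offsets = match_piston(corrupted, small_config)
        total = np.array([offsets[i] + deltas[i] for i in range(len(recs))])
        residual = np.angle(np.exp(1j * (total - total[0])))
        assert np.abs(residual).max() < 1e-6

    def test_matching_beats_no_matching(self, small_config, rng):
        recs = self._records(small_config, rng)
        deltas = rng.uniform(-np.pi, np.pi, len(recs))
        corrupted = [
            dataclasses.replace(r, field=r.field.with_values(
                r.field.values * np.exp(1j * d)))
            for r, d in zip(recs, deltas)
        ]
        reference = synthesize(recs, small_config, match_pistons=False).image
        with_m = synthesize(corrupted, small_config, match_pistons=True).image
        without = synthesize(corrupted, small_config, match_pistons=False).image
        rms_with = np.sqrt(np.mean((with_m - reference) ** 2))
        rms_without = np.sqrt(np.mean((without - reference) ** 2))
        assert rms_with < rms_without

    def test_disconnected_tile_raises(self, small_config, rng):
        cfg = small_config
        sample = checkerboard(cfg.n_pixels, rng)
        c1, c2 = cfg.tilt_for_carrier_bins(5 * cfg.mask_radius_bins, 0.0)
        ills = [ZernikeCoefficients.zeros(),
                ZernikeCoefficients.zeros().replace(c1=c1, c2=c2)]
        recs = [measure_illumination(sample, c, cfg, index=i)
                for i, c in enumerate(ills)]
        with pytest.raises(TileOverlapError):
            match_piston(recs, cfg)


class TestReconstruct:
    def test_psf_shrinks_with_illumination_count(self, small_config, rng):
        """Point-object PSF width shrinks monotonically as the synthetic
        aperture grows (the resolution gain of aperture synthesis)."""
        cfg = small_config
        n = cfg.n_pixels
        point = np.zeros((n, n))
        point[n // 2 - 1:n // 2 + 1, n // 2 - 1:n // 2 + 1] = 1.0

        def psf_width(half):
            ills = grid_illuminations(cfg, spacing_bins=14, half=half)
            syn = reconstruct(point, ills, cfg, mode="ideal")
            img = syn.image
            cols = np.arange(n) - n // 2
            return (img.sum(axis=0) * cols**2).sum() / img.sum()

        widths = [psf_width(h) for h in (0, 1, 2)]
        assert widths[0] > widths[1] > widths[2]

    def test_compensated_beats_uncompensated(self, small_config):
        cfg = small_config
        rng = np.random.default_rng(3)
        sample = (rng.random((cfg.n_pixels, cfg.n_pixels)) > 0.5).astype(float)
        ills = grid_illuminations(cfg, spacing_bins=12, half=1, rng=rng,
                                  aberration_scale=6.0)
        ideal = reconstruct(sample, ills, cfg, mode="ideal").image
        comp = reconstruct(sample, ills, cfg, mode="gt-compensated").image
        uncomp = reconstruct(sample, ills, cfg, mode="uncompensated").image
        rms_comp = np.sqrt(np.mean((comp - ideal) ** 2))
        rms_uncomp = np.sqrt(np.mean((uncomp - ideal) ** 2))
        assert rms_comp < rms_uncomp

    def test_unknown_mode_rejected(self, tiny_config, rng):
        with pytest.raises(ValueError):
            reconstruct(checkerboard(tiny_config.n_pixels, rng),
                        [ZernikeCoefficients.zeros()], tiny_config, mode="bogus")

    def test_predicted_mode_needs_model(self, tiny_config, rng):
        with pytest.raises(ValueError):
            reconstruct(checkerboard(tiny_config.n_pixels, rng),
                        [ZernikeCoefficients.zeros()], tiny_config, mode="predicted")
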