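"""Fourier-domain synthetic-aperture synthesis with aberration compensation.

Each angled illumination measures a low-pass tile of the sample spectrum
shifted by the illumination carrier.  Reconstruction proceeds per
illumination: remove the image-degrading aberration phase (Zernike orders
3..9, predicted or ground truth), demodulate by the carrier so the tile
lands at its true position in the synthesized Fourier domain, align the
unobservable piston phase against the already-accumulated spectrum on the
overlap, and accumulate.  Overlapping tiles are averaged (per-pixel weight
map), which keeps the effective passband weighting flat; the synthesized
image is the inverse transform of the averaged spectrum.

Carriers are rounded to integer Fourier bins for tile placement; any
sub-pixel residual is left in the tile as a phase ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .holography import make_holograms, recover_field
from .wave_optics import (ComplexField, OpticalConfig, Wavevector, cfft2,
                          icfft2, circular_mask, aperture_field,
                          image_through_system)
from .zernike import ZernikeCoefficients, aperture_mask, phase_map


@dataclass(frozen=True)
class IlluminationRecord:
    """One illumination: carrier, coefficients, and the recovered field."""

    index: int
    carrier_bins: tuple[float, float]  # (fx, fy) displacement in Fourier bins
    field: ComplexField  # recovered (and possibly compensated) object field
    true_coeffs: ZernikeCoefficients | None = None
    predicted_coeffs: ZernikeCoefficients | None = None
    wavevector: Wavevector | None = None

    @property
    def carrier_radius(self) -> float:
        return float(np.hypot(*self.carrier_bins))


@dataclass(frozen=True)
class SynthesizedField:
    """Accumulated spectrum, per-pixel tile count, and the synthesized image."""

    spectrum: np.ndarray  # averaged, DC-centered
    weight: np.ndarray  # integer accumulation count
    field: ComplexField  # Usyn = inverse transform of the averaged spectrum

    @property
    def image(self) -> np.ndarray:
        """Synthesized intensity |Usyn|^2."""
        return self.field.intensity


class TileOverlapError(ValueError):
    """A tile's spectral support does not touch the already-matched region."""


def compensate(record: IlluminationRecord, coeffs: ZernikeCoefficients,
               config: OpticalConfig) -> IlluminationRecord:
    """Remove the image-degrading aberration (orders 3..9) from a record.

    Multiplies the recovered field by exp(-j phase(c3..c9)) on the aperture
    grid (the CCD grid is congruent to it in this model).  The carrier terms
    c1, c2 are *not* removed — they place the tile during synthesis — and
    piston is handled by :func:`match_piston`.
    """
    phi = phase_map(coeffs, config.grid, terms=range(3, 10))
    values = record.field.values * np.exp(-1j * phi)
    return _dc_replace(record, field=record.field.with_values(values))


def _tile_support(n: int, mask_radius_bins: float,
                  center_bins: tuple[int, int]) -> np.ndarray:
    cx, cy = center_bins
    # fx varies along columns, fy along rows with +fy upward
    cols = np.arange(n)[None, :] - (n // 2 + cx)
    rows = (n // 2 - cy) - np.arange(n)[:, None]
    return (cols**2 + rows**2 <= mask_radius_bins**2)


def _demodulate(field: ComplexField, carrier_bins: tuple[float, float]) -> \
        tuple[np.ndarray, tuple[int, int]]:
    """Demodulate by the integer part of the carrier; return (spectrum, center).

    The returned center is where the tile lands in the synthesized Fourier
    domain (bins relative to DC); the sub-pixel residual stays in the tile
    as a phase ramp.
    """
    n = field.n_pixels
    fx, fy = carrier_bins
    ix, iy = int(round(fx)), int(round(fy))
    cols = np.arange(n)[None, :] - n // 2
    rows = n // 2 - np.arange(n)[:, None]  # y up
    ramp = np.exp(-2j * np.pi * (ix * cols + iy * rows) / n)
    return cfft2(field.values * ramp), (-ix, -iy)


def match_piston(records: list[IlluminationRecord], config: OpticalConfig,
                 reference_index: int | None = None,
                 amplitude_floor: float = 0.01) -> dict[int, float]:
    """Piston offsets that make the tiles mutually phase-consistent.

    Tiles are visited center-out (carrier radius ascending, ties by index;
    the reference tile, offset 0, is the first visited unless
    ``reference_index`` forces it).  Each offset is the amplitude-weighted
    mean phase difference between the accumulated spectrum and the new tile
    over their overlap, restricted to pixels above ``amplitude_floor`` times
    the tile's peak magnitude.  Returns {record index: offset}; applying
    exp(+j offset) to each tile before accumulation aligns the pistons.
    """
    offsets, _, _ = _accumulate(records, config, True, reference_index,
                                amplitude_floor)
    return offsets


def _accumulate(records, config, do_match, reference_index, amplitude_floor):
    if not records:
        raise ValueError("need at least one illumination record")
    n = records[0].field.n_pixels
    for r in records:
        if r.field.n_pixels != n:
            raise ValueError("records must share one grid")
    order = sorted(records, key=lambda r: (r.carrier_radius, r.index))
    if reference_index is not None:
        order.sort(key=lambda r: r.index != reference_index)
    acc = np.zeros((n, n), dtype=complex)
    weight = np.zeros((n, n), dtype=np.int64)
    offsets: dict[int, float] = {}
    for pos, rec in enumerate(order):
        spec, center = _demodulate(rec.field, rec.carrier_bins)
        support = _tile_support(n, config.mask_radius_bins, center)
        delta = 0.0
        if do_match and pos > 0:
            floor = amplitude_floor * np.abs(spec[support]).max(initial=0.0)
            overlap = support & (weight > 0) & (np.abs(spec) > floor)
            if not overlap.any():
                raise TileOverlapError(
                    f"tile {rec.index} has no overlap with the matched region")
            avg = acc[overlap] / weight[overlap]
            corr = np.vdot(spec[overlap], avg)  # sum conj(tile) * acc
            delta = float(np.angle(corr))
        offsets[rec.index] = delta
        acc[support] += spec[support] * np.exp(1j * delta)
        weight[support] += 1
    return offsets, acc, weight


def synthesize(records: list[IlluminationRecord], config: OpticalConfig,
               match_pistons: bool = True,
               reference_index: int | None = None,
               amplitude_floor: float = 0.01) -> SynthesizedField:
    """Accumulate demodulated tiles into the synthesized spectrum and image."""
    _, acc, weight = _accumulate(records, config, match_pistons,
                                 reference_index, amplitude_floor)
    spectrum = np.where(weight > 0, acc / np.maximum(weight, 1), 0.0)
    f0 = records[0].field
    field = ComplexField(icfft2(spectrum), f0.pixel_pitch, f0.wavelength, "synthesized")
    return SynthesizedField(spectrum, weight, field)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def measure_illumination(sample: np.ndarray, coeffs: ZernikeCoefficients,
                         config: OpticalConfig, index: int = 0,
                         reference_amplitude: float | None = None) -> IlluminationRecord:
    """Simulate one SA-DHM measurement: aberrated illumination of the sample,
    4-f imaging through the NA mask, 4-step holography, field recovery."""
    grid = config.grid
    illum = aperture_mask(grid) * np.exp(1j * phase_map(coeffs, grid))
    obj = ComplexField(np.asarray(sample) * illum, config.pixel_pitch,
                       config.wavelength, "sample")
    ccd = image_through_system(obj, config)
    Ar = reference_amplitude
    if Ar is None:
        Ar = float(np.abs(ccd.values).mean()) or 1.0
    holos = make_holograms(ccd, Ar)
    recovered = recover_field(holos)
    uo = recovered.with_values(recovered.values / (4 * Ar), plane_label="object")
    return IlluminationRecord(
        index=index, carrier_bins=config.carrier_bins(coeffs), field=uo,
        true_coeffs=coeffs,
    )


def reconstruct(sample: np.ndarray,
                illuminations: list[ZernikeCoefficients],
                config: OpticalConfig,
                mode: str = "gt-compensated",
                model=None,
                match_pistons: bool = True) -> SynthesizedField:
    """Full SA-DHM reconstruction of ``sample`` under a set of illuminations.

    Parameters
    ----------
    sample : (N, N) array
        Complex (or binary amplitude) transmittance of the target.
    illuminations : list of ZernikeCoefficients
        True aberration (including carrier tilts c1, c2 and piston c0) of
        each illumination beam.
    mode : {"ideal", "uncompensated", "gt-compensated", "predicted"}
        ``ideal`` simulates aberration-free illuminations (carriers and
        piston only); the others simulate the aberrated beams and differ in
        which coefficients are used to compensate orders 3..9: none, ground
        truth, or the estimator's prediction from the illumination's
        diffraction triplet.
    model : ZernikeRegressor, required for mode="predicted".

    Carrier placement always uses the ground-truth tilts, and the unlearnable
    piston is aligned by overlap matching during synthesis.
    """
    if mode not in ("ideal", "uncompensated", "gt-compensated", "predicted"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "predicted" and model is None:
        raise ValueError("mode='predicted' needs a trained model")
    records = []
    for i, coeffs in enumerate(illuminations):
        sim_coeffs = coeffs
        if mode == "ideal":
            sim_coeffs = ZernikeCoefficients.zeros().replace(
                c0=coeffs[0], c1=coeffs[1], c2=coeffs[2])
        rec = measure_illumination(sample, sim_coeffs, config, index=i)
        if mode == "gt-compensated":
            rec = compensate(rec, coeffs, config)
        elif mode == "predicted":
            from .dataset_gen import render_triplet
            triplet = render_triplet(coeffs, config)
            pred = model.predict_coefficients(triplet)
            rec = compensate(rec, pred, config)
        records.append(rec)
    return synthesize(records, config, match_pistons=match_pistons)
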