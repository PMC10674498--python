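"""Scalar-diffraction engine for the simplified SA-DHM simulation.

Models the layout used to generate training data and reconstructions: an
aberrated plane wave truncated by a circular aperture, a 4-f relay (objective
f1, tube lens f2) with a circular NA mask in the common Fourier plane, a
camera (CCD) plane conjugate to the aperture, and an out-of-focus observation
plane a distance d beyond the camera.

Conventions
-----------
* All transverse lengths are in micrometres internally; focal lengths and
  propagation distances are accepted in millimetres (the units the optical
  layout is usually quoted in) and converted.
* FFTs are DC-centered: pixel (N/2, N/2), 0-based, is DC.  ``cfft2``/
  ``icfft2`` wrap the shift bookkeeping and use the unitary ("ortho")
  normalisation so propagation and lens transforms preserve energy.
* The 4-f chain is modelled as: aperture-plane field -> Fourier transform
  (lens f1, aperture in its front focal plane) -> NA mask -> inverse
  transform (lens f2) -> CCD field on the *same* pixel grid; the lateral
  magnification -f2/f1 is absorbed into the grid bookkeeping rather than
  resampled, so synthetic-aperture synthesis stays pure index arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace as _dc_replace
from pathlib import Path

import numpy as np
import yaml
from scipy import fft as _fft

from .zernike import UnitDiskGrid, ZernikeCoefficients, aperture_mask, phase_map

MM_TO_UM = 1000.0


def cfft2(x: np.ndarray) -> np.ndarray:
    """Unitary DC-centered 2-D FFT (input and output both DC-centered)."""
    return _fft.fftshift(_fft.fft2(_fft.ifftshift(x), norm="ortho"))


def icfft2(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cfft2`."""
    return _fft.fftshift(_fft.ifft2(_fft.ifftshift(x), norm="ortho"))


@dataclass(frozen=True)
class ComplexField:
    """Sampled 2-D complex amplitude with grid metadata."""

    values: np.ndarray
    pixel_pitch: float  # um
    wavelength: float  # um
    plane_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("field must be a square 2-D array")
        if self.pixel_pitch <= 0 or self.wavelength <= 0:
            raise ValueError("pixel pitch and wavelength must be positive")
        object.__setattr__(self, "values", v.astype(complex, copy=False))

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def energy(self) -> float:
        """Total energy sum |U|^2 * pitch^2."""
        return float(np.sum(np.abs(self.values) ** 2) * self.pixel_pitch**2)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    def with_values(self, values: np.ndarray, plane_label: str | None = None,
                    pixel_pitch: float | None = None) -> "ComplexField":
        return ComplexField(
            values,
            self.pixel_pitch if pixel_pitch is None else pixel_pitch,
            self.wavelength,
            self.plane_label if plane_label is None else plane_label,
        )


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry of the simulated SA-DHM (defaults: the full-scale layout)."""

    n_pixels: int = 2240
    pixel_pitch: float = 1.0  # um
    wavelength: float = 0.532  # um
    f1: float = 10.0  # mm, objective focal length
    f2: float = 200.0  # mm, tube lens focal length
    defocus_d: float = 10.0  # mm, out-of-focus observation distance
    fourier_mask_diameter_px: int = 224
    aperture_radius_px: float = 560.0  # Zernike aperture radius on the grid

    def __post_init__(self) -> None:
        for name in ("pixel_pitch", "wavelength", "f1", "f2", "defocus_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fourier_mask_diameter_px > self.n_pixels:
            raise ValueError("Fourier mask larger than grid")
        if 2 * self.aperture_radius_px > self.n_pixels:
            raise ValueError("aperture does not fit in grid")

    # --- derived geometry -------------------------------------------------
    @property
    def grid(self) -> UnitDiskGrid:
        return UnitDiskGrid(self.n_pixels, self.aperture_radius_px)

    @property
    def freq_bin(self) -> float:
        """Fourier bin spacing, cycles/um."""
        return 1.0 / (self.n_pixels * self.pixel_pitch)

    @property
    def mask_radius_bins(self) -> float:
        return self.fourier_mask_diameter_px / 2.0

    @property
    def mask_na(self) -> float:
        """Numerical aperture realised by the Fourier-plane mask."""
        return self.wavelength * self.mask_radius_bins * self.freq_bin

    @property
    def grid_na(self) -> float:
        """NA corresponding to the full simulation bandwidth (grid Nyquist)."""
        return self.wavelength * (self.n_pixels / 2.0) * self.freq_bin

    @property
    def max_tilt_rad(self) -> float:
        """Aliasing bound on |c1|,|c2|: pi rad/pixel across the aperture."""
        return np.pi * self.aperture_radius_px

    def carrier_bins(self, coeffs: ZernikeCoefficients) -> tuple[float, float]:
        """Carrier displacement (fx, fy) in Fourier bins for tilt terms (c2, c1).

        A tilt phase c*rho*cos(phi) (= c*x/R) shifts the spectrum by
        c*N/(2 pi R) bins along fx; the sin term shifts along fy likewise.
        """
        s = self.n_pixels / (2 * np.pi * self.aperture_radius_px)
        return coeffs[2] * s, coeffs[1] * s

    def tilt_for_carrier_bins(self, fx_bins: float, fy_bins: float) -> tuple[float, float]:
        """Inverse of :meth:`carrier_bins`: (c1, c2) giving that displacement."""
        s = 2 * np.pi * self.aperture_radius_px / self.n_pixels
        return fy_bins * s, fx_bins * s

    def is_dark_field(self, coeffs: ZernikeCoefficients) -> bool:
        """True when the carrier falls outside the objective NA mask."""
        fx, fy = self.carrier_bins(coeffs)
        return bool(np.hypot(fx, fy) > self.mask_radius_bins)

    def validate_tilt_range(self, tilt_max: float) -> None:
        if tilt_max > self.max_tilt_rad:
            raise ValueError(
                f"tilt range {tilt_max:g} rad aliases: limit is pi*R = "
                f"{self.max_tilt_rad:g} rad for aperture radius "
                f"{self.aperture_radius_px:g} px"
            )

    @classmethod
    def scaled(cls, factor: int = 4, **overrides) -> "OpticalConfig":
        """Preset scaled down by ``factor`` preserving all dimensionless ratios
        (mask/grid, aperture/grid, carrier bins per radian of tilt)."""
        base = cls()
        kw = dict(
            n_pixels=base.n_pixels // factor,
            fourier_mask_diameter_px=base.fourier_mask_diameter_px // factor,
            aperture_radius_px=base.aperture_radius_px / factor,
        )
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **kw) -> "OpticalConfig":
        return _dc_replace(self, **kw)

    # --- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "OpticalConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))


@dataclass(frozen=True)
class Wavevector:
    """Illumination wavevector (kx, ky, kz) in rad/mm, kz > 0."""

    kx: float
    ky: float
    kz: float

    def __post_init__(self) -> None:
        if self.kz <= 0:
            raise ValueError("kz must be positive (forward propagation)")

    @property
    def magnitude(self) -> float:
        return float(np.sqrt(self.kx**2 + self.ky**2 + self.kz**2))

    def transverse_freq_cycles_per_um(self) -> tuple[float, float]:
        """(fx, fy) spatial frequency of the carrier in cycles/um."""
        return self.kx / (2 * np.pi * MM_TO_UM), self.ky / (2 * np.pi * MM_TO_UM)


def illumination_wavevector(M: float, xi: float, yi: float, WD: float,
                            wavelength: float) -> Wavevector:
    """Wavevector of the directional plane wave from a condenser point source.

    A micro-lens at (xi, yi) mm, imaged with magnification M, acts as a point
    source at working distance WD mm of the condenser; the emerging collimated
    beam has wavevector k * (M xi, M yi, WD)/||(M xi, M yi, WD)||, with
    k = 2 pi / wavelength (wavelength in um; result in rad/mm).

    """
    if WD <= 0:
        raise ValueError("working distance must be positive")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    k = 2 * np.pi / (wavelength / MM_TO_UM)  # rad/mm
    v = np.array([M * xi, M * yi, WD], dtype=float)
    v *= k / np.linalg.norm(v)
    return Wavevector(*v)


# ---------------------------------------------------------------------------
# propagation and imaging
# ---------------------------------------------------------------------------

def _freq_grids(n: int, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    f = (np.arange(n) - n // 2) / (n * pitch)
    return f[None, :], f[:, None]  # fx along columns, fy along rows


def propagate(field: ComplexField, distance: float) -> ComplexField:
    """Band-limited angular-spectrum propagation over ``distance`` mm.

    Uses the exact transfer function exp(j 2 pi d sqrt(1/lambda^2 - f^2))
    with evanescent components suppressed and the Matsushima band limit
    applied to avoid transfer-function aliasing at long distances.
    """
    if distance == 0:
        return field
    d_um = distance * MM_TO_UM
    n, pitch, lam = field.n_pixels, field.pixel_pitch, field.wavelength
    fx, fy = _freq_grids(n, pitch)
    f2 = fx**2 + fy**2
    arg = 1.0 / lam**2 - f2
    prop = arg > 0
    kz = np.sqrt(np.where(prop, arg, 0.0))
    H = np.where(prop, np.exp(2j * np.pi * np.abs(d_um) * kz), 0.0)
    if d_um < 0:
        H = np.conj(H)
    # Matsushima & Shimobaba band limit
    df = 1.0 / (n * pitch)
    f_limit = 1.0 / (lam * np.sqrt((2 * df * abs(d_um)) ** 2 + 1.0))
    H = np.where((np.abs(fx) <= f_limit) & (np.abs(fy) <= f_limit), H, 0.0)
    out = icfft2(cfft2(field.values) * H)
    return field.with_values(out)


def lens_fourier(field: ComplexField, focal_length: float) -> ComplexField:
    """Field in the back focal plane of an ideal lens (front-focal-plane input).

    Output sampling is lambda*f/(N*pitch) per pixel; the unitary transform
    preserves energy up to a fixed constant.
    """
    if focal_length <= 0:
        raise ValueError("focal length must be positive")
    out_pitch = field.wavelength * focal_length * MM_TO_UM / (field.n_pixels * field.pixel_pitch)
    return field.with_values(cfft2(field.values), plane_label="fourier",
                             pixel_pitch=out_pitch)


def circular_mask(n: int, diameter_px: float, center: tuple[float, float] | None = None) -> np.ndarray:
    if center is None:
        center = (n / 2, n / 2)
    rows = np.arange(n)[:, None] - center[0]
    cols = np.arange(n)[None, :] - center[1]
    return (rows**2 + cols**2 <= (diameter_px / 2.0) ** 2).astype(float)


def apply_na_mask(field: ComplexField, mask_diameter_px: int) -> ComplexField:
    """Zero the amplitude outside the centered circular NA mask."""
    if mask_diameter_px > field.n_pixels:
        raise ValueError("mask diameter exceeds grid")
    return field.with_values(field.values * circular_mask(field.n_pixels, mask_diameter_px))


def image_through_system(field: ComplexField, config: OpticalConfig) -> ComplexField:
    """Linear 4-f imaging operator: aperture plane -> NA mask -> CCD plane.

    The -f2/f1 magnification is absorbed into grid bookkeeping; the CCD field
    is returned on the same pixel grid as the input.
    """
    spec = cfft2(field.values)
    spec *= circular_mask(field.n_pixels, config.fourier_mask_diameter_px)
    return field.with_values(icfft2(spec), plane_label="ccd")


def aperture_field(aberration: ZernikeCoefficients, config: OpticalConfig) -> ComplexField:
    """Unit-amplitude aberrated field truncated by the circular aperture."""
    grid = config.grid
    values = aperture_mask(grid) * np.exp(1j * phase_map(aberration, grid))
    return ComplexField(values, config.pixel_pitch, config.wavelength, "aperture")


def simulate_observation(
    aberration: ZernikeCoefficients, config: OpticalConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, ComplexField]:
    """Simulate the three intensity observations of one illumination.

    Returns ``(fourier_intensity, focal_intensity, defocus_intensity,
    camera_field)``: |.|^2 in the Fourier plane after the NA mask, |.|^2 on
    the CCD plane, |.|^2 at defocus_d beyond the CCD plane, and the complex
    CCD field.  Deterministic for fixed inputs.
    """
    field = aperture_field(aberration, config)
    spec = cfft2(field.values) * circular_mask(config.n_pixels, config.fourier_mask_diameter_px)
    fourier_intensity = np.abs(spec) ** 2
    camera = field.with_values(icfft2(spec), plane_label="ccd")
    focal_intensity = camera.intensity
    defocus_intensity = propagate(camera, config.defocus_d).intensity
    return fourier_intensity, focal_intensity, defocus_intensity, camera
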