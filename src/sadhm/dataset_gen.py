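"""Labelled training-data generation for the aberration estimator.

Each sample is a three-channel 224x224 raster — intensity in the Fourier
plane (after the NA mask), on the focal (CCD) plane, and in an out-of-focus
plane — labelled with the ten Zernike coefficients that produced it.

Sampling ranges (defaults) for the random coefficients:

    c0        ~ U[-pi, pi]          piston
    c1, c2    ~ U[-1200, 1200]      tilts / carriers, bounded to avoid aliasing
    c3 .. c9  ~ U[-48, 48]          image-degrading aberrations

Optionally the high-order terms are scaled in proportion to the carrier
magnitude (``proportional_to_tilt``); the fixed range is the default.
With this geometry (mask radius a tenth of the grid) the carrier falls
outside the objective NA for almost every draw, so nearly all samples are
dark-field: only aperture-edge diffraction reaches the camera.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .wave_optics import (ComplexField, OpticalConfig, cfft2, icfft2,
                          circular_mask, propagate, aperture_field,
                          simulate_observation)
from .zernike import N_TERMS, ZernikeCoefficients

IMAGE_SIZE = 224


@dataclass(frozen=True)
class SamplingRanges:
    """Symmetric uniform sampling ranges for the ten coefficients."""

    z0_range: float = np.pi
    tilt_range: float = 1200.0
    high_order_range: float = 48.0
    proportional_to_tilt: bool = False

    def __post_init__(self) -> None:
        if min(self.z0_range, self.tilt_range, self.high_order_range) < 0:
            raise ValueError("ranges must be non-negative half-widths")

    @classmethod
    def scaled(cls, factor: int = 4, **overrides) -> "SamplingRanges":
        """Ranges for the scaled-down optical preset: the tilt bound shrinks
        with the aperture (aliasing limit pi*R) and the high-order bound
        shrinks with it to preserve the aberration-to-carrier ratio."""
        kw = dict(tilt_range=1200.0 / factor, high_order_range=48.0 / factor)
        kw.update(overrides)
        return cls(**kw)


def ranges_for_config(config: OpticalConfig,
                      proportional_to_tilt: bool = False) -> SamplingRanges:
    """Sampling ranges matched to a geometry: the full-scale ranges shrunk by
    the aperture ratio so the tilt bound keeps clear of the aliasing limit
    and the aberration-to-carrier ratio stays fixed."""
    factor = 560.0 / config.aperture_radius_px
    ranges = SamplingRanges(tilt_range=1200.0 / factor,
                            high_order_range=48.0 / factor,
                            proportional_to_tilt=proportional_to_tilt)
    config.validate_tilt_range(ranges.tilt_range)
    return ranges


def sample_coefficients(ranges: SamplingRanges,
                        rng: np.random.Generator | int) -> ZernikeCoefficients:
    """Draw one random coefficient vector; reproducible under a seed."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    c = np.empty(N_TERMS)
    c[0] = rng.uniform(-ranges.z0_range, ranges.z0_range)
    c[1:3] = rng.uniform(-ranges.tilt_range, ranges.tilt_range, size=2)
    c[3:] = rng.uniform(-ranges.high_order_range, ranges.high_order_range, size=7)
    if ranges.proportional_to_tilt and ranges.tilt_range > 0:
        c[3:] *= np.hypot(c[1], c[2]) / (ranges.tilt_range * np.sqrt(2))
    return ZernikeCoefficients(c)


@dataclass(frozen=True)
class DiffractionTriplet:
    """One training unit: 3-channel image + coefficient label."""

    image: np.ndarray  # (size, size, 3) in [0, 1]; channels Fourier/focal/defocus
    label: ZernikeCoefficients
    dark_field: bool

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=np.float32)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("image must be (H, W, 3)")
        if img.min() < -1e-6 or img.max() > 1 + 1e-6:
            raise ValueError("channels must be normalized to [0, 1]")
        object.__setattr__(self, "image", img)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _resize(x: np.ndarray, size: int) -> np.ndarray:
    n = x.shape[0]
    if n == size:
        return x
    if n % size == 0:  # integer area binning
        b = n // size
        return x.reshape(size, b, size, b).mean(axis=(1, 3))
    return ndimage.zoom(x, size / n, order=1, grid_mode=True, mode="grid-constant")


def _observe_channels(coeffs: ZernikeCoefficients, config: OpticalConfig,
                      method: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw (uncropped Fourier, focal, defocus) intensities for one illumination.

    ``method='spectral'`` evaluates the focal and defocus intensities on the
    grid spanned by the NA-masked spectrum padded to twice the mask diameter.
    The camera field is band-limited by the mask, so this is the exact field
    on a coarser sampling (and the intensity at its Nyquist rate) — it avoids
    full-grid transforms for every sample.  ``method='direct'`` runs the
    full-grid simulation.
    """
    if method == "direct":
        fourier_i, focal_i, defocus_i, _ = simulate_observation(coeffs, config)
        return fourier_i, focal_i, defocus_i
    if method != "spectral":
        raise ValueError(f"unknown method {method!r}")
    n, d = config.n_pixels, config.fourier_mask_diameter_px
    field = aperture_field(coeffs, config)
    spec = cfft2(field.values) * circular_mask(n, d)
    c = n // 2
    crop = spec[c - d // 2:c + d // 2, c - d // 2:c + d // 2]
    fourier_i = np.abs(crop) ** 2
    side = 2 * d
    pad = np.zeros((side, side), dtype=complex)
    pad[side // 2 - d // 2:side // 2 + d // 2,
        side // 2 - d // 2:side // 2 + d // 2] = crop
    coarse_pitch = n * config.pixel_pitch / side
    camera = ComplexField(icfft2(pad), coarse_pitch, config.wavelength, "ccd")
    focal_i = camera.intensity
    defocus_i = propagate(camera, config.defocus_d).intensity
    return fourier_i, focal_i, defocus_i


def render_triplet(coeffs: ZernikeCoefficients, config: OpticalConfig,
                   out_size: int = IMAGE_SIZE,
                   method: str = "spectral") -> DiffractionTriplet:
    """Simulate one illumination and assemble the normalized 3-channel image.

    The Fourier channel is the masked Fourier-plane intensity cropped to the
    mask's bounding square (224 px native at the full-scale geometry) and
    resampled to ``out_size``; the focal and defocus channels are resampled
    to ``out_size`` by area binning.  Each channel is min-max normalized
    independently, which deliberately discards the global intensity scale
    (and with it any trace of the piston term c0).
    """
    fourier_i, focal_i, defocus_i = _observe_channels(coeffs, config, method)
    if method == "direct":
        n, d = config.n_pixels, config.fourier_mask_diameter_px
        c = n // 2
        fourier_i = fourier_i[c - d // 2:c + d // 2, c - d // 2:c + d // 2]
    channels = [_resize(ch, out_size) for ch in (fourier_i, focal_i, defocus_i)]
    image = np.stack([_minmax(ch) for ch in channels], axis=-1)
    return DiffractionTriplet(image, coeffs, config.is_dark_field(coeffs))


def generate_triplets(n_samples: int, ranges: SamplingRanges,
                      config: OpticalConfig, seed: int,
                      out_size: int = IMAGE_SIZE,
                      method: str = "spectral",
                      progress: bool = False):
    """Generate ``n_samples`` triplets in memory.

    Returns ``(X, y, dark)``: images (n, out_size, out_size, 3) float32,
    labels (n, 10) float64, and the dark-field flags (n,) bool.
    """
    config.validate_tilt_range(ranges.tilt_range)
    rng = np.random.default_rng(seed)
    X = np.empty((n_samples, out_size, out_size, 3), dtype=np.float32)
    y = np.empty((n_samples, N_TERMS))
    dark = np.empty(n_samples, dtype=bool)
    iterator = range(n_samples)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="triplets")
    for i in iterator:
        coeffs = sample_coefficients(ranges, rng)
        t = render_triplet(coeffs, config, out_size=out_size, method=method)
        X[i] = t.image
        y[i] = coeffs.c
        dark[i] = t.dark_field
    return X, y, dark


# ---------------------------------------------------------------------------
# on-disk datasets
# ---------------------------------------------------------------------------

def config_hash(config: OpticalConfig, ranges: SamplingRanges) -> str:
    blob = json.dumps({"config": config.to_dict(), "ranges": asdict(ranges)},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_dataset(n_samples: int, ranges: SamplingRanges, config: OpticalConfig,
                  seed: int, out_dir: str | Path,
                  image_format: str = "png", progress: bool = True) -> dict:
    """Write a labelled dataset: images/NNNNNN.png + labels.csv + manifest.json.

    Deterministic under ``seed``; resumable (existing image files are kept,
    the label table is always rewritten in full so it cannot desynchronize).
    The image filename embeds the label-row id.  ``image_format`` may be
    ``png`` (lossless, default) or ``bmp``; both store 8-bit RGB rasters.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if image_format not in ("png", "bmp"):
        raise ValueError("image_format must be 'png' or 'bmp'")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    config.validate_tilt_range(ranges.tilt_range)

    rng = np.random.default_rng(seed)
    rows = []
    iterator = range(n_samples)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="dataset")
    for i in iterator:
        coeffs = sample_coefficients(ranges, rng)  # always draw: keeps resume deterministic
        name = f"{i:06d}.{image_format}"
        path = out_dir / "images" / name
        dark = config.is_dark_field(coeffs)
        if not path.exists():
            t = render_triplet(coeffs, config)
            iio.imwrite(path, np.round(t.image * 255).astype(np.uint8))
        rows.append({"id": i, "image": name,
                     **{f"c{n}": coeffs[n] for n in range(N_TERMS)},
                     "dark_field": dark})
    labels = pd.DataFrame(rows)
    labels.to_csv(out_dir / "labels.csv", index=False)
    manifest = {
        "n_samples": n_samples,
        "seed": seed,
        "image_format": image_format,
        "image_size": IMAGE_SIZE,
        "ranges": asdict(ranges),
        "config": config.to_dict(),
        "config_hash": config_hash(config, ranges),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_dataset(manifest_path: str | Path):
    """Load a dataset written by :func:`build_dataset` into arrays.

    Returns ``(X, y, dark, manifest)`` with X in [0, 1] float32.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    labels = pd.read_csv(root / "labels.csv")
    X = np.stack([
        iio.imread(root / "images" / name).astype(np.float32) / 255.0
        for name in labels["image"]
    ])
    y = labels[[f"c{n}" for n in range(N_TERMS)]].to_numpy()
    return X, y, labels["dark_field"].to_numpy(dtype=bool), manifest
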