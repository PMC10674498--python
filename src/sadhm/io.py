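"""Persistence helpers: complex fields as HDF5, intensity maps as 16-bit PNG."""

from __future__ import annotations

from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

from .wave_optics import ComplexField


def save_field(field: ComplexField, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=field.values.real, compression="gzip")
        f.create_dataset("imag", data=field.values.imag, compression="gzip")
        f.attrs["pixel_pitch_um"] = field.pixel_pitch
        f.attrs["wavelength_um"] = field.wavelength
        f.attrs["plane_label"] = field.plane_label


def load_field(path: str | Path) -> ComplexField:
    with h5py.File(path, "r") as f:
        values = f["real"][:] + 1j * f["imag"][:]
        return ComplexField(values, float(f.attrs["pixel_pitch_um"]),
                            float(f.attrs["wavelength_um"]),
                            str(f.attrs.get("plane_label", "")))


def save_intensity_png(intensity: np.ndarray, path: str | Path,
                       log_scale: bool = False) -> None:
    """Write an intensity map as a 16-bit PNG (optionally log-magnitude)."""
    x = np.asarray(intensity, dtype=float)
    if log_scale:
        x = np.log10(x + x.max() * 1e-9 + 1e-300)
    lo, hi = x.min(), x.max()
    x = (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)
    iio.imwrite(Path(path), np.round(x * 65535).astype(np.uint16))
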