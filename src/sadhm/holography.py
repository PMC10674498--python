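"""Parallel 4-step phase-shifting interferometry.

Four holograms of the object field against a phase-stepped reference,

    I_n = |Ao|^2 + Ar^2 + 2 Ao Ar cos(theta_o + s n pi/2),   n = 1..4,

and recovery of the complex object field from the two quadrature differences
(I1 - I3) + j (I2 - I4).

Sign convention: with the literal shift +n pi/2 (s = +1) the quadrature
combination evaluates to -4j Ar Ao exp(-j theta_o); with s = -1 it is
-4j Ar Ao exp(+j theta_o).  The physically meaningful contract is exact
recovery, so :func:`recover_field` applies the fixed constant (and, for
s = +1, a conjugation) that makes

    recover_field(make_holograms(U, Ar)) == 4 Ar U

hold to machine precision.  The default shift sign is -1 and the constant is
a single multiplication by j; both are frozen here and in the docs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .wave_optics import ComplexField


@dataclass(frozen=True)
class HologramSet:
    """Four phase-shifted intensity maps I1..I4 and the reference amplitude."""

    I: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    reference_amplitude: float | np.ndarray
    shift_sign: int = -1
    pixel_pitch: float = 1.0
    wavelength: float = 0.532

    def __post_init__(self) -> None:
        maps = tuple(np.asarray(m, dtype=float) for m in self.I)
        if len(maps) != 4:
            raise ValueError("expected four holograms")
        shape = maps[0].shape
        for m in maps:
            if m.shape != shape:
                raise ValueError("hologram maps must share one grid")
            if np.any(m < -1e-12):
                raise ValueError("intensities must be non-negative")
        if self.shift_sign not in (+1, -1):
            raise ValueError("shift_sign must be +1 or -1")
        if np.any(np.asarray(self.reference_amplitude) < 0):
            raise ValueError("reference amplitude must be >= 0")
        object.__setattr__(self, "I", maps)

    # --- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write I1..I4 as 16-bit PNGs plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        peak = max(float(m.max()) for m in self.I) or 1.0
        for n, m in enumerate(self.I, start=1):
            iio.imwrite(directory / f"I{n}.png",
                        np.round(m / peak * 65535).astype(np.uint16))
        sidecar = {
            "reference_amplitude": float(np.mean(self.reference_amplitude)),
            "shift_sign": self.shift_sign,
            "intensity_scale": peak,
            "pixel_pitch_um": self.pixel_pitch,
            "wavelength_um": self.wavelength,
        }
        (directory / "holograms.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "HologramSet":
        directory = Path(directory)
        meta = json.loads((directory / "holograms.json").read_text())
        maps = tuple(
            iio.imread(directory / f"I{n}.png").astype(float) / 65535 * meta["intensity_scale"]
            for n in range(1, 5)
        )
        return cls(maps, meta["reference_amplitude"], meta["shift_sign"],
                   meta["pixel_pitch_um"], meta["wavelength_um"])


def make_holograms(object_field: ComplexField, Ar: float | np.ndarray = 1.0,
                   shift_sign: int = -1) -> HologramSet:
    """Form the four phase-shifted holograms of ``object_field``.

    ``Ar`` is the (normally uniform, collimated) reference amplitude; a
    per-pixel map is accepted.
    """
    if shift_sign not in (+1, -1):
        raise ValueError("shift_sign must be +1 or -1")
    Ar = np.asarray(Ar, dtype=float)
    if np.any(Ar < 0):
        raise ValueError("reference amplitude must be >= 0")
    Ao = np.abs(object_field.values)
    theta = np.angle(object_field.values)
    dc = Ao**2 + Ar**2
    maps = tuple(
        dc + 2 * Ao * Ar * np.cos(theta + shift_sign * n * np.pi / 2)
        for n in range(1, 5)
    )
    return HologramSet(maps, Ar if Ar.ndim else float(Ar), shift_sign,
                       object_field.pixel_pitch, object_field.wavelength)


def recover_field(holos: HologramSet, shift_sign: int | None = None) -> ComplexField:
    """Recover the complex object field from a 4-step hologram set.

    Returns 4 * Ar * Ao * exp(j theta_o): the quadrature combination
    (I1 - I3) + j (I2 - I4) followed by the frozen constant for the set's
    shift convention.  Divide by 4 * Ar to obtain the unit-scale field.
    """
    if shift_sign is None:
        shift_sign = holos.shift_sign
    I1, I2, I3, I4 = holos.I
    q = (I1 - I3) + 1j * (I2 - I4)
    # s = -1: q = -4j Ar Ao e^{+j theta}  ->  * j
    # s = +1: q = -4j Ar Ao e^{-j theta}  ->  conj then * (-j)
    values = 1j * q if shift_sign == -1 else -1j * np.conj(q)
    return ComplexField(values, holos.pixel_pitch, holos.wavelength, "recovered")
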