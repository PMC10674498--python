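"""Zernike basis on a circular aperture.

The ten lowest Zernike terms parameterise the phase of the illumination beam
over the circular aperture that defines the unit disk.  The basis used here is
the *non-normalised* polynomial set

====  =================  =========================
 n    polynomial         common name
====  =================  =========================
 0    1                  piston
 1    rho sin(phi)       y tilt (carrier)
 2    rho cos(phi)       x tilt (carrier)
 3    rho^2 sin(2 phi)   oblique astigmatism
 4    2 rho^2 - 1        defocus
 5    rho^2 cos(2 phi)   vertical astigmatism
 6    rho^3 sin(3 phi)   vertical trefoil
 7    (3 rho^3 - 2 rho) sin(phi)   vertical coma
 8    (3 rho^3 - 2 rho) cos(phi)   horizontal coma
 9    rho^3 cos(3 phi)   oblique trefoil
====  =================  =========================

Coefficients are phase in **radians at the rim of the unit disk** (rho = 1 at
the aperture edge).  This is deliberately not the Noll/OSA orthonormal
convention: coefficient values elsewhere in the package (sampling ranges,
carrier/tilt arithmetic) are defined against exactly these polynomials.

Axis convention: phi is measured counter-clockwise from the +x (column) axis
with y increasing upward, i.e. for a map indexed ``[row, col]`` the physical
y coordinate is ``center_row - row``.  Under this convention the tilt term
``c1`` creates a carrier along +y and ``c2`` along +x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_TERMS = 10

NAMES = (
    "piston",
    "tilt_y",
    "tilt_x",
    "astigmatism_oblique",
    "defocus",
    "astigmatism_vertical",
    "trefoil_vertical",
    "coma_vertical",
    "coma_horizontal",
    "trefoil_oblique",
)


@dataclass(frozen=True)
class ZernikeCoefficients:
    """A 10-vector of Zernike weights c0..c9 (radians at the disk rim)."""

    c: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        if c.shape != (N_TERMS,):
            raise ValueError(f"expected {N_TERMS} coefficients, got shape {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "c", c)

    @classmethod
    def zeros(cls) -> "ZernikeCoefficients":
        return cls(np.zeros(N_TERMS))

    @classmethod
    def from_dict(cls, d: dict) -> "ZernikeCoefficients":
        c = np.zeros(N_TERMS)
        for k, v in d.items():
            c[int(k)] = float(v)
        return cls(c)

    def __getitem__(self, n: int) -> float:
        return float(self.c[n])

    def __add__(self, other: "ZernikeCoefficients") -> "ZernikeCoefficients":
        return ZernikeCoefficients(self.c + other.c)

    def __neg__(self) -> "ZernikeCoefficients":
        return ZernikeCoefficients(-self.c)

    def replace(self, **terms: float) -> "ZernikeCoefficients":
        """Return a copy with individual terms overridden, e.g. ``replace(c4=1.0)``."""
        c = self.c.copy()
        for k, v in terms.items():
            if not (k.startswith("c") and k[1:].isdigit()):
                raise KeyError(k)
            c[int(k[1:])] = v
        return ZernikeCoefficients(c)

    @property
    def tilt_magnitude(self) -> float:
        """Euclidean norm of the two carrier (tilt) terms."""
        return float(np.hypot(self.c[1], self.c[2]))

    # --- persistence -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"n": list(range(N_TERMS)), "value": self.c.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "ZernikeCoefficients":
        d = json.loads(Path(path).read_text())
        c = np.zeros(N_TERMS)
        c[np.asarray(d["n"], dtype=int)] = d["value"]
        return cls(c)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"n": range(N_TERMS), "value": self.c}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ZernikeCoefficients":
        df = pd.read_csv(path)
        c = np.zeros(N_TERMS)
        c[df["n"].to_numpy(dtype=int)] = df["value"].to_numpy(dtype=float)
        return cls(c)


@dataclass(frozen=True)
class UnitDiskGrid:
    """Pixel grid carrying the unit-disk normalisation of the aperture.

    rho = (radial distance from ``center`` in pixels) / ``aperture_radius_px``,
    so rho = 1 exactly at the aperture rim.  ``center`` defaults to
    (N/2, N/2) in 0-based coordinates, matching a DC-centered FFT layout.
    """

    n_pixels: int
    aperture_radius_px: float
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.aperture_radius_px <= 0:
            raise ValueError("aperture radius must be positive")
        if 2 * self.aperture_radius_px > self.n_pixels:
            raise ValueError("aperture does not fit in grid")
        if self.center is None:
            object.__setattr__(self, "center", (self.n_pixels / 2, self.n_pixels / 2))

    def polar(self) -> tuple[np.ndarray, np.ndarray]:
        """(rho, phi) maps for the grid; phi CCW from +x, y up."""
        rows = np.arange(self.n_pixels)[:, None]
        cols = np.arange(self.n_pixels)[None, :]
        y = self.center[0] - rows  # y increases upward
        x = cols - self.center[1]
        rho = np.hypot(x, y) / self.aperture_radius_px
        phi = np.arctan2(y, x)
        return rho, phi


def basis(n: int, rho, phi):
    """Evaluate Zernike term ``n`` (0..9) at polar coordinates (rho, phi).

    Defined for any rho >= 0; callers mask to rho <= 1.
    """
    if not 0 <= n < N_TERMS:
        raise IndexError(f"Zernike index {n} outside 0..{N_TERMS - 1}")
    rho = np.asarray(rho, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if n == 0:
        return np.ones(np.broadcast(rho, phi).shape)
    if n == 1:
        return rho * np.sin(phi)
    if n == 2:
        return rho * np.cos(phi)
    if n == 3:
        return rho**2 * np.sin(2 * phi)
    if n == 4:
        return 2 * rho**2 - 1
    if n == 5:
        return rho**2 * np.cos(2 * phi)
    if n == 6:
        return rho**3 * np.sin(3 * phi)
    if n == 7:
        return (3 * rho**3 - 2 * rho) * np.sin(phi)
    if n == 8:
        return (3 * rho**3 - 2 * rho) * np.cos(phi)
    return rho**3 * np.cos(3 * phi)


def aperture_mask(grid: UnitDiskGrid) -> np.ndarray:
    """Binary mask: 1 where rho <= 1 (inside the circular aperture), else 0."""
    rho, _ = grid.polar()
    return (rho <= 1.0).astype(float)


def phase_map(coeffs: ZernikeCoefficients, grid: UnitDiskGrid, terms=None) -> np.ndarray:
    """Phase map (radians) of the aberration inside the aperture; 0 outside.

    Parameters
    ----------
    terms
        Optional iterable of term indices to include (default: all ten).
        ``terms=range(3, 10)`` gives the image-degrading part with the
        piston and the two carriers excluded.
    """
    rho, phi = grid.polar()
    inside = rho <= 1.0
    out = np.zeros_like(rho)
    idx = range(N_TERMS) if terms is None else terms
    for n in idx:
        cn = coeffs[n]
        if cn != 0.0:
            out += cn * basis(n, rho, phi)
    out[~inside] = 0.0
    return out
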