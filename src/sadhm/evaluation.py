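"""Resolution targets and MTF measurement for reconstruction quality.

The linear bar chart stacks horizontal bands of vertical bars whose spatial
frequency increases band by band (21 to 500 lp/mm on the default 1 um grid;
500 lp/mm, a 2-pixel period, is the grid Nyquist).  Modulation per band is
measured on the reconstructed *intensity* with robust percentile extremes
(95th/5th of the row-averaged profile) rather than raw min/max, which
suppresses coherent ringing at bar edges.  A spoke (Siemens star) chart
provides a continuous frequency sweep: the local line-pair frequency at
radius r is n_spokes / (2 pi r).
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BarChartSpec:
    """Layout of a linear bar chart confined to a centered square region.

    ``periods_px`` are the bar-pair periods in pixels (even duty cycle:
    period//2 bright columns per period... periods need not be even; bars
    are ``period/2`` wide to the nearest pixel).  Frequencies in lp/mm
    follow from the pixel pitch: f = 1000 / (period_px * pitch_um).
    """

    periods_px: tuple = (48, 26, 16, 10, 6, 4, 2)
    pixel_pitch: float = 1.0  # um
    region_side: int = 784  # side of the centered square holding the bands
    guard_periods: float = 2.0  # blank guard between bands, in periods

    def __post_init__(self) -> None:
        p = np.asarray(self.periods_px)
        if np.any(p < 2):
            raise ValueError("periods below 2 px exceed the grid Nyquist")
        if np.any(np.diff(p) >= 0):
            raise ValueError("periods must be strictly decreasing (frequencies increasing)")

    @property
    def frequencies_lpmm(self) -> np.ndarray:
        return 1000.0 / (np.asarray(self.periods_px, dtype=float) * self.pixel_pitch)

    def band_layout(self, n_pixels: int) -> list[dict]:
        """Row ranges of each band on an n_pixels grid (bands stacked in y)."""
        k = len(self.periods_px)
        top = (n_pixels - self.region_side) // 2
        left = top
        band_h = self.region_side // k
        layout = []
        for b, period in enumerate(self.periods_px):
            guard = int(np.ceil(self.guard_periods * period))
            y0 = top + b * band_h
            y1 = y0 + band_h - guard
            if y1 - y0 < 4:
                raise ValueError(f"band {b}: guard leaves no room (period {period})")
            layout.append({"band": b, "period_px": period,
                           "frequency_lpmm": 1000.0 / (period * self.pixel_pitch),
                           "y0": y0, "y1": y1,
                           "x0": left, "x1": left + self.region_side})
        return layout


@dataclass(frozen=True)
class MTFCurve:
    """Modulation ratio per chart band."""

    frequency_lpmm: np.ndarray
    mtf: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_lpmm": self.frequency_lpmm, "mtf": self.mtf})

    def at(self, frequency_lpmm: float) -> float:
        i = int(np.argmin(np.abs(self.frequency_lpmm - frequency_lpmm)))
        if abs(self.frequency_lpmm[i] - frequency_lpmm) > 0.05 * frequency_lpmm:
            raise KeyError(f"no band near {frequency_lpmm} lp/mm")
        return float(self.mtf[i])


def make_bar_chart(spec: BarChartSpec, n_pixels: int) -> np.ndarray:
    """Binary amplitude bar target (1 = transparent bars, 0 = opaque)."""
    if spec.region_side > n_pixels:
        raise ValueError("chart region larger than grid")
    chart = np.zeros((n_pixels, n_pixels))
    for band in spec.band_layout(n_pixels):
        period = band["period_px"]
        cols = np.arange(band["x0"], band["x1"])
        bars = ((cols - band["x0"]) % period) < max(period // 2, 1)
        chart[band["y0"]:band["y1"], band["x0"]:band["x1"]] = bars[None, :]
    return chart


def make_spoke_chart(n_spokes: int, radius_px: float, n_pixels: int,
                     inner_radius_px: float = 1.0) -> np.ndarray:
    """Binary spoke (Siemens star) target with ``n_spokes``-fold symmetry.

    Alternating transparent/opaque sectors; local line-pair frequency at
    radius r is n_spokes / (2 pi r).  The singular center (r < inner_radius)
    is excluded (opaque).
    """
    if n_spokes < 1:
        raise ValueError("need at least one spoke")
    if 2 * radius_px > n_pixels:
        raise ValueError("spoke chart does not fit grid")
    c = n_pixels / 2
    y = c - np.arange(n_pixels)[:, None]
    x = np.arange(n_pixels)[None, :] - c
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    sectors = np.floor(phi / (2 * np.pi) * 2 * n_spokes).astype(int) % 2
    chart = (sectors == 0) & (r <= radius_px) & (r >= inner_radius_px)
    return chart.astype(float)


def spoke_local_frequency_lpmm(n_spokes: int, radius_mm: float) -> float:
    """Local line-pair frequency of a spoke chart at the given radius."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    return n_spokes / (2 * np.pi * radius_mm)


def measure_mtf(intensity: np.ndarray, spec: BarChartSpec,
                percentile: float = 95.0, row_margin: int = 2,
                col_margin_periods: float = 1.0) -> MTFCurve:
    """Per-band modulation of a reconstructed intensity image.

    For each band the profile across the bars is the mean over the band's
    rows; modulation = (Ihi - Ilo) / (Ihi + Ilo) with Ihi/Ilo the
    ``percentile``-th / (100-percentile)-th percentiles of the profile.
    Values above 1 (coherent overshoot) are reported as measured, not
    clipped.
    """
    intensity = np.asarray(intensity)
    n = intensity.shape[0]
    freqs, mtfs = [], []
    for band in spec.band_layout(n):
        if band["y1"] > n or band["x1"] > n:
            raise ValueError(f"band {band['band']} outside image")
        margin = int(np.ceil(col_margin_periods * band["period_px"]))
        rows = slice(band["y0"] + row_margin, band["y1"] - row_margin)
        cols = slice(band["x0"] + margin, band["x1"] - margin)
        profile = intensity[rows, cols].mean(axis=0)
        hi = np.percentile(profile, percentile)
        lo = np.percentile(profile, 100 - percentile)
        denom = hi + lo
        mtfs.append(float((hi - lo) / denom) if denom > 0 else 0.0)
        freqs.append(band["frequency_lpmm"])
    return MTFCurve(np.asarray(freqs), np.asarray(mtfs))
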