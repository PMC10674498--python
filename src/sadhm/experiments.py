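"""Canned simulation studies: bar-chart MTF under aperture synthesis.

These drive the full pipeline (illumination -> 4-f imaging -> 4-step
holography -> recovery -> compensation -> piston matching -> synthesis) on
the linear resolution chart and measure per-band modulation.  They are used
by the acceptance script and the heavier tests, and are convenient entry
points for exploring the geometry.
"""

from __future__ import annotations

import numpy as np

from .evaluation import BarChartSpec, MTFCurve, make_bar_chart, measure_mtf
from .sa_reconstruction import SynthesizedField, reconstruct
from .wave_optics import OpticalConfig
from .zernike import ZernikeCoefficients


def full_scale_chart(config: OpticalConfig | None = None) -> BarChartSpec:
    """The 21-500 lp/mm chart on the full-scale grid (1 um pitch): bar
    periods 48..2 px, inscribed in the illumination aperture."""
    if config is None:
        config = OpticalConfig()
    side = int(config.aperture_radius_px * np.sqrt(2)) // 2 * 2
    return BarChartSpec(periods_px=(48, 26, 16, 10, 6, 4, 2),
                        pixel_pitch=config.pixel_pitch, region_side=side)


def scaled_chart(config: OpticalConfig) -> BarChartSpec:
    """A reduced chart (62.5-125 lp/mm) for the quarter-scale preset."""
    side = int(config.aperture_radius_px * np.sqrt(2)) // 2 * 2
    return BarChartSpec(periods_px=(16, 12, 10, 8),
                        pixel_pitch=config.pixel_pitch, region_side=side)


def line_carriers(config: OpticalConfig, coverage_fraction: float = 0.625,
                  spacing_bins: float | None = None) -> list[tuple[float, float]]:
    """Carriers tiling the f_x axis out to ``coverage_fraction`` of Nyquist.

    The bar chart is one-dimensional, so covering the f_x axis suffices;
    tiles are spaced to overlap (default spacing = 1.34 x mask radius) and
    the outermost carrier is placed so the synthesized support reaches
    exactly the requested coverage.
    """
    r = config.mask_radius_bins
    reach = coverage_fraction * config.n_pixels / 2 - r  # outermost carrier
    if spacing_bins is None:
        spacing_bins = round(1.34 * r)
    positions = list(np.arange(0.0, reach - 1e-9, spacing_bins))
    positions.append(reach)
    carriers = [(0.0, 0.0)]
    for p in positions[1:]:
        carriers += [(round(p), 0.0), (-round(p), 0.0)]
    return carriers


def square_carriers(config: OpticalConfig, spacing_bins: float,
                    half: int = 2) -> list[tuple[float, float]]:
    """A (2*half+1)^2 grid of carriers with the given Fourier-bin spacing."""
    return [(fx * spacing_bins, fy * spacing_bins)
            for fy in range(-half, half + 1) for fx in range(-half, half + 1)]


def illuminations_from_carriers(config: OpticalConfig,
                                carriers: list[tuple[float, float]],
                                seed: int | None = None,
                                aberration_range: float = 0.0,
                                piston: bool = True) -> list[ZernikeCoefficients]:
    """Coefficient vectors with the given carriers; optionally random piston
    and high-order aberrations drawn uniformly from +-aberration_range."""
    rng = np.random.default_rng(seed)
    ills = []
    for fx, fy in carriers:
        c = np.zeros(10)
        c[1], c[2] = config.tilt_for_carrier_bins(fx, fy)
        if piston:
            c[0] = rng.uniform(-np.pi, np.pi)
        if aberration_range:
            c[3:] = rng.uniform(-aberration_range, aberration_range, 7)
        ills.append(ZernikeCoefficients(c))
    return ills


def bar_chart_mtf(config: OpticalConfig, chart: BarChartSpec,
                  illuminations: list[ZernikeCoefficients],
                  mode: str = "ideal",
                  model=None) -> tuple[MTFCurve, SynthesizedField]:
    """Reconstruct the bar chart under the given illuminations and measure
    the per-band MTF of the synthesized intensity."""
    target = make_bar_chart(chart, config.n_pixels)
    syn = reconstruct(target, illuminations, config, mode=mode, model=model)
    return measure_mtf(syn.image, chart), syn
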