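# Methods

## Optical model

The simulated instrument is the simplified SA-DHM used for data generation
and reconstruction studies: an illumination plane wave with phase aberration
`φ(ρ,ϕ) = Σₙ₌₀⁹ cₙ Zₙ(ρ,ϕ)` truncated by a circular aperture, a 4-f relay
(objective f1, tube lens f2) with a circular NA mask in the common Fourier
plane, a camera conjugate to the aperture, and an out-of-focus observation
plane a distance d past the camera.  Defaults: 2240 × 2240 grid, 1 µm pixel
pitch, λ = 0.532 µm, f1/f2/d = 10/200/10 mm, mask diameter 224 px.  With
frequency bin 1/(N·pitch), the mask radius corresponds to NA
= λ·112/2240 µm⁻¹ = 0.0266 and the full grid to NA 0.266.

Conventions (these matter because sin/cos Zernike terms swap under axis
flips):

* ρ = 1 exactly at the aperture rim; the aperture radius defaults to a
  quarter of the grid (560 px at full scale) so aperture-edge diffraction is
  well sampled.  The physical aperture diameter is a free parameter of the
  simulation, stored in config and dataset manifests.
* ϕ is measured counter-clockwise from the +x (column) axis with y upward:
  for arrays indexed `[row, col]`, y = center_row − row.
* FFTs are DC-centered and unitary; pixel (N/2, N/2) is DC.
* The Zernike basis is the non-normalised polynomial set (piston, tilts,
  astigmatisms, defocus 2ρ²−1, comas (3ρ³−2ρ)·sin/cos, trefoils); all
  coefficients are radians of phase at the disk rim.  The basis is *not*
  Noll/OSA-orthonormal because all coefficient ranges and carrier arithmetic
  in the package are defined against the printed polynomials.  Note the
  defocus term has zero mean over the disk, so terms 0..9 are in fact
  pairwise orthogonal (unnormalised).
* A tilt coefficient c (radians at the rim) displaces the spectrum by
  c·N/(2πR) Fourier bins; the aliasing bound |c| ≤ πR is enforced at
  config-validation time.
* The 4-f chain is modelled as Fourier transform → mask → inverse
  transform, with the −f2/f1 magnification absorbed into grid bookkeeping,
  so aperture, Fourier and camera grids stay congruent and Fourier-domain
  synthesis is pure index arithmetic.  The aperture is taken as the front
  focal plane of the objective (exact Fourier relation), rather than
  propagating an extra f1 of free space first.
* Free-space propagation uses the exact angular-spectrum transfer function
  with evanescent cutoff and the Matsushima band limit.  The Fresnel
  approximation is avoided; d = 10 mm at 1 µm sampling is comfortably within
  angular-spectrum validity.

## Holography

Four phase-shifted holograms `I_n = |A_o|² + A_r² + 2A_oA_r cos(θ_o + s·nπ/2)`,
n = 1..4, are combined as `(I₁−I₃) + j(I₂−I₄)`.  With the literal shift
s = +1 this equals −4j·A_r·A_o·e^{−jθ_o}; the quadrature pair and the
reconstruction formula are only consistent up to a fixed constant and
conjugation.  The package freezes the physically meaningful contract
instead: the default shift sign is −1 and recovery multiplies by j, so that
`recover(make(U, A_r)) = 4·A_r·U` holds to machine precision for both shift
conventions (s = +1 additionally conjugates).  The reference amplitude is
spatially uniform by default (collimated reference); in the pipeline it is
set to the mean object amplitude, mirroring how a variable attenuator would
balance the arms for fringe contrast.

## Synthetic-aperture synthesis

Each recovered field is compensated by `exp(−jφ₃..₉)` (orders 3..9 only:
the tilts place the tile and piston is handled separately), demodulated by
the integer-bin part of its carrier (sub-pixel residuals stay in the tile as
a phase ramp), Fourier transformed, and accumulated on the disc-shaped
support of the shifted NA mask.  Overlapping tiles are **averaged** via a
per-pixel weight map rather than summed: plain summation would double-weight
overlaps and ripple the effective MTF, whereas averaging keeps a flat unit
passband, which is what makes the synthesized MTF track the aberration-free
reference.

Piston (Z₀) is invisible in intensity and unlearnable by the estimator, so
it is aligned geometrically: tiles are visited center-out (carrier radius
ascending, ties by index) and each receives the phase offset that best
matches the already-accumulated spectrum over the tile overlap — an
amplitude-weighted mean phase difference over overlap pixels above 1 % of
the tile's peak magnitude.  A single reference point would be noise-fragile;
the weighted overlap mean is the robust generalisation.  A tile whose
support does not touch the matched region raises a topology error naming the
tile.  Offsets are exact (≲ 1e-6 rad) for noiseless tiles because
overlapping tiles sample identical spectrum values.

With the true coefficients, compensation after low-pass filtering is not
algebraically exact (multiplication by the aberration phase does not commute
with the NA mask), but the residual shrinks as tile overlap grows; with a
25-tile grid at 0.86× mask-radius spacing the compensated MTF tracks the
aberration-free synthesis to well within 0.05 per band.

## Synthetic training data

One training sample is a 3-channel image: Fourier-plane intensity (after the
NA mask, cropped to the mask's bounding square — 224 px native at full
scale), focal-plane intensity, and out-of-focus intensity, each resampled to
224×224 (focal/defocus by area binning) and min-max normalised per channel.
Per-channel normalisation deliberately discards the global intensity scale;
together with the intensity-only observation this makes the piston term
carry *zero* information into the image, which is why Z₀ is unlearnable.

Coefficients are drawn uniformly: c₀ ∈ [−π, π]; tilts c₁, c₂ ∈ [−1200, 1200]
rad (bounded by the aliasing limit π·560 ≈ 1760 rad of the full-scale
aperture); c₃..c₉ ∈ [−48, 48] rad, optionally rescaled in proportion to the
carrier magnitude (off by default — the fixed range matches the sampling
rule as stated).  Under this geometry the carrier exceeds the mask for
~98 % of draws, so almost all samples are dark-field; the dark-field flag is
computed analytically from the carrier radius.

The focal and defocus channels are computed on the grid spanned by the
NA-masked spectrum padded to twice the mask diameter.  Because the camera
field is strictly band-limited by the mask, this coarse-grid evaluation is
exact for the field and samples the intensity at its Nyquist rate; it makes
sample generation ~20× cheaper than full-grid transforms, and a test
cross-checks it against the direct simulation.

A 4× scaled-down preset (560 px grid, 56 px mask, 140 px aperture) preserves
every dimensionless ratio (mask/grid, aperture/grid, bins-per-radian of
tilt, mask NA).  Its sampling ranges divide the tilt *and* high-order bounds
by the same factor: the tilt bound is forced by the scaled aliasing limit
(π·140 ≈ 440 rad), and scaling the aberration bound with it preserves the
printed 48/1200 aberration-to-carrier ratio.  Piston keeps [−π, π].

## Aberration estimator

The regressor is a residual CNN trained with Adam on mean-squared error over
the ten outputs, each label divided by a per-coefficient scale (by default
the training-set max |c|, i.e. the sampling half-ranges): without scaling the
tilt terms would dominate the loss by a factor of several hundred.  The
network library (`sadhm.nn`) is implemented in numpy — im2col convolutions,
batch normalisation, average-pool downsampling, global-average-pool linear
head — with hand-written reverse-mode gradients verified against finite
differences.  Two architectures are provided: `resnet-small` (stem + three
residual stages of widths 16/32/64 on 56×56 inputs; the default, trainable
on one CPU core) and `resnet50` (the bottleneck [3,4,6,3] topology with a
10-output head for full-scale runs; downsampling uses average pooling since
the library deliberately omits strided convolution).  Inputs are raw [0, 1]
channel values average-pooled to the network input size; optimiser defaults
are Adam 1e-3–2e-3 with step decay, batch 32–64.  The final linear layer is
zero-initialised, so the untrained network predicts zero and the epoch-0
validation MSE equals the second moment of the scaled labels — a clean
baseline for measuring learning.

At the package's CPU study scale (2,500 quarter-scale triplets, 30 epochs)
the carrier terms c₁, c₂ are learned strongly (validation MSE falls by
roughly an order of magnitude — the carrier is encoded geometrically in
where the diffraction arc sits), defocus c₄ improves about twofold, and the
remaining high-order terms improve only marginally; c₀ stays exactly at the
constant-zero baseline, as the invariance argument predicts.  The aggregate
c₁..c₉ error reduction grows steadily with dataset size in a 600 → 2,500
sample scaling study and is clearly data-limited at this scale: recovering
the high-order aberrations to small error is a 10⁵-sample, full-ResNet-50
regime, supported here by configuration but far outside a single-CPU
budget.  A flatten regression head (kept as an option) memorises rather
than generalises at these dataset sizes, which is why global average
pooling is the default.

## Resolution evaluation

The linear bar chart stacks bands of vertical binary bars with integer pixel
periods (48, 26, 16, 10, 6, 4, 2 px at full scale → 20.8 to 500 lp/mm;
2 px is the grid Nyquist).  Bands sit inside the square inscribed in the
illumination aperture, with blank guards of ≥ 2 periods between bands
against cross-talk.  Modulation per band is (Ihi − Ilo)/(Ihi + Ilo) on the
synthesized *intensity*, with Ihi/Ilo the 95th/5th percentiles of the
row-averaged profile — robust extremes suppress coherent edge ringing that
raw min/max would amplify.  Values above 1 are reported as measured.  The
spoke chart provides a continuous sweep with local frequency
n_spokes/(2πr).

For the headline full-geometry experiment the bar chart is one-dimensional,
so the illumination carriers tile the f_x axis only: nine carriers at 0,
±150, ±300, ±450 and ±588 bins place the outermost tile edge at 700 bins =
62.5 % of the 500 lp/mm bandwidth.  An isotropic 2-D tiling to the same
radius would take ~90 illuminations and add nothing for a 1-D target.
Problem sizes throughout (grid factors 16/8/4 in the tests, 2,500 training
samples, 25-tile compensation study) are the package's chosen CPU-scale
study conditions; all dimensionless geometry is preserved at every scale.

## Known limitations

* Scalar, monochromatic, paraxial model: no polarisation, no chromatic
  effects, no condenser/objective pupil apodisation, no camera noise —
  hooks for noise are deliberately absent since the study data are
  noise-free simulations.  Passing tests show correctness of the model and
  estimator *within this idealised world*; real instruments add shot/read
  noise, pixel demosaicing of the polarisation camera, and field-dependent
  aberrations that the generator does not emulate.
* Per-channel min-max normalisation discards absolute intensity; any
  quantity encoded only in global scale is unlearnable by design.
* Compensation multiplies the *recovered* (band-limited) field by the
  conjugate aberration phase; for aberrations whose local spectral spread
  approaches the mask radius this is approximate, and residuals grow with
  aberration magnitude and shrink with tile overlap.
* Carrier placement uses ground-truth (or predicted) tilts rounded to
  integer Fourier bins; no data-driven carrier refinement is attempted.
* No iterative (ptychography-style) refinement: the pipeline is strictly
  feed-forward, by design.
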