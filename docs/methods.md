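# Methods

This note documents the models, estimators and numerical choices behind
stripesim, in the order data flows through the pipeline.

## Image-formation model

The sample is a non-negative fluorophore density `S(r)` on a 2-D pixel
grid.  Illumination is a sinusoidal stripe field
`I(r) = I0·(1 + m·cos(2π k_θ·r + φ))` with frequency vector `k_θ`
(cycles/px), modulation depth `m ∈ [0, 1]` and mean intensity `I0`.
Emission `I·S` is blurred by the incoherent PSF, applied as a
multiplication with the OTF in the frequency domain, i.e. as a
*circular* convolution.  Circular boundaries are a deliberate
simplification: they keep the forward model exactly consistent with the
Fourier-domain reconstruction, so oracle tests can demand 1e-6-level
agreement.  Real acquisitions have open boundaries; the estimators do
not rely on circularity (they use windowless demodulation and
correlation magnitudes), but edge beads in real data will behave
slightly differently than simulated ones.

Detector noise is Poisson shot noise at a configurable photon budget
(`photons` per unit noiseless intensity, default 500) followed by
Gaussian read noise (`read_noise_dn`, default 2 DN with 1 DN ≡ 1
photon).  Negative values after read noise are clipped at zero, as a
real camera would.

Coordinates: `x` is the column, `y` the row.  All real-space phases and
all spectra are referenced to the image center (pixel `(H//2, W//2)`),
which physically is the optical axis.  This choice matters: with a
corner origin, a frequency-estimate error `δ` leaks into every phase
estimate through the half-image lever arm (`2π·δ·N/2` radians in the
worst case); with a centered origin the leakage is proportional to the
sample's centroid offset instead, typically near zero.  The FFT helpers
implement this as a symmetric DFT (`ifftshift` before, `fftshift`
after).

## Optical model

`k_c = 2·NA/λ` in cycles/length (the angular-frequency convention
`2π·2NA/λ` found elsewhere differs only by 2π and is never stored).  The
analytic OTF is the circular-pupil autocorrelation
`O(ρ) = (2/π)(arccos ρ − ρ√(1−ρ²))`, `ρ = |k|/k_c`, identically zero
beyond the cutoff.  The sharp cutoff is the point: support-extension
claims are only falsifiable against an OTF that is exactly zero outside
`k_c`.  A measured OTF (2-D float TIFF, DC-centered) can replace it; it
is renormalised to `OTF(0) = 1` and negative values are clipped with a
warning.  Defaults NA = 1.4, λ = 520 nm (a green emitter such as Alexa
Fluor 488), pixel 45 nm — an oil-immersion objective sampled just above
Nyquist (`k_c` = 0.242 cycles/px).

## Synthetic targets

* `beads` — isolated single-pixel emitters with a minimum separation
  (default 40 beads, 14 px apart); positions are recorded so tests can
  measure per-bead FWHM.  Emulates a sub-resolution bead slide.
* `filaments` — random-walk curves of 1-px width (default 12 curves),
  a stand-in for labelled microtubule networks; spectrally dense with a
  dominant DC term, which is what makes blind parameter estimation
  well-posed.
* `spokes` — a Siemens-star radial target covering all orientations and
  a continuum of frequencies.
* `custom` — any caller-provided non-negative array.

What the generator does *not* emulate: open image boundaries,
photobleaching between frames, fixed-pattern and correlated camera
noise, out-of-focus background, sample drift, and DMD diffraction
effects.  Passing tests therefore demonstrate algorithmic correctness
under the stated model, not robustness to every experimental
nuisance — the preprocessing stage (histogram matching, median
filtering) addresses the mildest of these in real data.

Default acquisition geometry: orientations 0°, 60°, 120°, phase steps
0°, 120°, 240°, `|k_θ| = 0.8·k_c`, `m = 0.8`.  The stripe frequency is
specified in continuous cycles/px and evaluated in real space, so it is
*not* restricted to grid frequencies — essential for testing sub-pixel
estimation honestly.

## DMD patterns

Binary stripe rasterization: pixel on iff
`frac((x·cosθ + y·sinθ)/P − φ/2π) < duty/P`.  Phases are quantised to
whole-pixel shifts (`round(P·φ/2π)`); non-representable phases warn and
record the realised phase in the pattern metadata rather than erroring,
because downstream processing uses *estimated* phases anyway.  Exact
duty cycle is guaranteed only for axis-aligned orientations; oblique
stripes are thresholded continuous phase and rounded at boundaries with
a 1e-9 epsilon against float ties.  The minimum period for exact 120°
steps at 50 % duty is 6 px (period must be divisible by 3 for the step
and even for the duty), stepped 2 px at a time.

## Parameter estimation

Per orientation (3 frames):

1. **Mean subtraction.**  For equispaced phase steps the frame mean is
   exactly the widefield image, so residuals contain only the modulated
   bands.  This removes the sample's own spectrum from the peak
   neighbourhood, the dominant bias of naive phase-of-peak estimation.
2. **Coarse peak.**  Frames are Wiener pre-filtered
   (`conj(OTF)·D̃/(|OTF|+σ)`, σ = 0.01), separated with the *nominal*
   phases (0°/120°/240°; near-equispaced true steps contribute only a
   global phase factor, which cannot move a correlation peak), and the
   first-order band is cross-correlated against the zeroth order.  The
   correlation magnitude, masked to an annulus `0.3·k_c ≤ |k| ≤
   1.1·k_c` (hard-edged; the DC bin is always excluded), peaks at the
   signed stripe frequency.  Unlike an argmax on the raw spectrum this
   sums coherently over the whole band and survives strong OTF
   attenuation at `|k_θ|` — though for extremely sparse scenes (a
   handful of beads) the sample term can still win; parameter
   estimation should be performed on a dense scene, as it would be
   experimentally.
3. **Sub-pixel refinement.**  Bands are re-separated with per-frame
   phases read at the coarse peak, using *band-flattening* weights
   `OTF/(OTF² + σ)` instead of the OTF-shaped pre-filter: both bands
   were attenuated by the same `OTF(k)`, so dividing it out leaves
   near-unit envelopes.  The normalised (phase-only, stabilised by
   `|·| + 10⁻³·max`) cross-spectrum of the two bands is then a complex
   ramp `exp(i2π k_θ·r)` whose frequency is located by a local
   upsampled DFT: a 0.01-grid-cycle search within ±2 grid cycles of the
   coarse peak, then a second pass at 0.001 granularity.  If the
   optimum lands on the search border the estimator falls back to the
   coarse peak with a warning flag.  Noiseless accuracy on dense
   targets is below 0.01 grid cycles per axis.
4. **Phases.**  Each mean-subtracted frame is demodulated at the
   refined frequency (a single exact DFT coefficient, center
   referenced); the argument is the frame's stripe phase, wrapped to
   (−π, π].  Noiseless accuracy on dense 512² targets is better than
   2°, limited by residual frequency error and band overlap, not by the
   estimator itself.

The sign of `k_θ` is whichever half-plane the correlation peak falls
in; phases are automatically consistent with that choice, and flipping
both leaves the reconstruction invariant (comparisons against ground
truth canonicalise the sign first).

Modulation depth `m` is taken from configuration (default 0.8, matching
the simulator).  An experimental per-orientation estimate
(`2·|demodulation mean| / (DC·OTF(k_θ))`) is available behind
`estimate_m=True` but is not used by default.

The literal integer-bin operations — annulus-masked spectral argmax and
phase-of-peak at an integer coordinate — are exposed as
`find_modulation_peak` and `estimate_phase` with their own contracts;
`estimate_all` composes the refined variants described above.

## Reconstruction

Per orientation the 3×3 mixing matrix `M` (built from the three
estimated phases and `m`; rejected as singular if two phases coincide
within 1e-6 rad) is inverted once and applied pixelwise to the frame
spectra, yielding orders 0, +1, −1.  Spectra are embedded centered into
a `pad_factor`× larger grid (default 2×) so shifted bands are not
clipped — grid-cycle coordinates are preserved by the embedding, and
the output image is correspondingly upsampled.  The +1 band (content at
`+k_θ`) is shifted by `−k_θ` and the −1 band by `+k_θ`, each via the
Fourier shift theorem (inverse transform, complex ramp, forward
transform — exact for non-integer shifts).  Each band is paired with
the correspondingly shifted OTF (`OTF(k ± k_θ)`, bilinear off-grid
resampling, zero outside the original support).  All nine bands are
fused by the generalized Wiener filter with constant `w` (default 0.1
relative to the unit-normalised OTF) and the image is the real part of
the inverse transform; the discarded imaginary residue is reported and
is at float-epsilon level for exact parameters.  An optional triangle
apodization of the fused spectrum (default off) is available to damp
ringing.  The effective cutoff `k_c + max|k_θ|` is recorded on the
result.

Whether to fuse on the native or a padded grid was an open design
choice; padding was chosen because the extended support otherwise
aliases for `|k_θ| > (Nyquist − k_c)`, which the default geometry
violates.

Sign conventions (the `e^{+iφ}` weight on the `S̃(k−k_θ)` band, the
`∓k_θ` shift directions) are pinned by tests: a flipped sign widens
bead images and increases reconstruction error instead of shrinking
them.

## Backend contract

All element-wise kernels of the pipeline (add, multiply,
conjugate-multiply, magnitude, complex ramp, Wiener pre-filter ratio,
Wiener numerator/denominator terms) live in a registry and execute
through interchangeable backends: `serial` (whole-array numpy),
`threads` (the array tiled by a launch geometry of `ceil(size/dim)`
blocks per axis, default 32×32 threads per block, overhang masked;
disjoint output tiles make results bit-identical to serial), and `gpu`
(CuPy, feature-detected at runtime; its absence never breaks install or
tests).  The launch arithmetic itself is exposed (`launch_geometry`)
and tested, including the no-overhang case where the block size divides
the image size exactly.

## Preprocessing

Raw frames are histogram-matched (monotone quantile mapping) to a
reference frame — frame 0 by default, since nothing distinguishes the
frames a priori — and then median-filtered (default 3×3, reflected
edges).  Matching precedes filtering; both the order and the window are
configurable.  Matching equalises slow intensity drift across the nine
frames, which band separation would otherwise read as spurious
modulation; the median step suppresses impulsive detector noise.

## Numerical choices and degenerate inputs

* Wiener constants: `w = 0.1` (fusion), `σ = 0.01` (pre-filter).  Both
  are exposed; `w` trades noise amplification against passband
  flatness.
* Annulus radii 0.3/1.1 × `k_c`: hard-edged masks (the filter profile
  is not otherwise constrained by the method).
* Ties at binary stripe boundaries are broken toward "on" with a 1e-9
  epsilon.
* Unmodulated stacks (identical frames): estimation raises a
  no-peak error naming the orientation; reconstruction with nominal
  parameters degenerates cleanly to a Wiener deconvolution of the
  widefield image with empty sidebands.
* Constant histogram-match references, all-zero OTFs, non-finite image
  writes, duplicate separation phases and out-of-registry backend ops
  all raise typed errors rather than propagating garbage.

## Problem sizes

Unit tests run on 128²–256² grids; the end-to-end acceptance tests use
512² stacks (5 seeds for parameter recovery), the scale at which the
default optical geometry is comfortably sampled.  All randomness flows
from explicit integer seeds; every simulation is bit-reproducible.

## Known limitations

* 2-D only: no 3-D SIM, no optical sectioning, no TIRF variant.
* Linear SIM only (no saturated/nonlinear orders).
* The estimator assumes near-equispaced phase steps when building the
  nominal separation for coarse peak finding; grossly non-equispaced
  steps degrade the coarse stage (the refined per-frame phases still
  track moderate deviations).
* Blind estimation needs a spectrally dense scene; a few isolated
  beads are enough to *reconstruct* (given parameters) but not to
  *estimate* reliably.
* Circular convolution edge model, as discussed above.
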