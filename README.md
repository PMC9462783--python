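# stripesim

Structured illumination microscopy (SIM) reconstruction for stripe-pattern
acquisitions, together with everything needed to drive and validate it:
binary DMD pattern generation, a diffraction-limited optical model, a
forward simulator for synthetic data, raw-frame preprocessing,
illumination-parameter estimation and generalized-Wiener band fusion.

## Who this is for

Builders and users of DMD-based (digital micromirror device) SIM
microscopes: low-cost setups that project binary stripe patterns onto a
fluorescent sample, acquire 9 raw frames (3 stripe orientations × 3 phase
steps of 120°) and computationally fuse them into an image whose
resolution exceeds the diffraction limit.  The package is a library first
and a CLI (`stripesim`) second; every stage is testable on synthetic data
it generates itself, so correctness does not depend on access to a
microscope.

## The model

A fluorescence microscope is a low-pass filter: the detected image is
`D(r) = [I(r)·S(r)] ⊗ PSF(r)`, so its spectrum is cut off at
`k_c = 2·NA/λ` (cycles/length).  Illuminating with a sinusoidal stripe
field

```
I(r) = I0 · (1 + m·cos(2π k_θ·r + φ))
```

mixes three copies of the sample spectrum into each raw frame:

```
D̃(k) = I0·[ S̃(k) + (m/2)·e^{+iφ}·S̃(k−k_θ) + (m/2)·e^{−iφ}·S̃(k+k_θ) ]·OTF(k)
```

The shifted copies carry sample frequencies from beyond the cutoff into
the passband.  Per orientation, the three phase-stepped frames form a
3×3 linear system with mixing matrix `M` (rows `[1, (m/2)e^{iφ_n},
(m/2)e^{−iφ_n}]`); inverting it separates the bands, the Fourier shift
theorem slides the first orders back to their true origin (exactly, for
sub-pixel `k_θ`), and a generalized Wiener filter fuses all nine bands:

```
S_SIM(k) = Σ_n OTF_n(k)*·R_n(k) / ( Σ_n |OTF_n(k)|² + w ),    S_s(r) = F⁻¹[S_SIM]
```

The spectral support of `S_SIM` reaches `k_c + |k_θ|`.

Because the actual stripe phase and frequency at the sample differ from
what was programmed on the DMD, both are estimated from the data: the
modulation peak is located by cross-correlating the separated first- and
zeroth-order bands, refined to sub-pixel precision by phase-only
correlation (the normalised band cross-spectrum is a complex ramp at
`k_θ`), and per-frame phases are read off as the *phase of peak* — the
complex argument of the spectrum at the modulation peak.

On the DMD itself the patterns are binary: a stripe period of 6 mirrors
(3 on, 3 off) is the smallest that realises exact 120° phase steps as
whole-mirror shifts (2 px per step).

## Worked example

```python
import numpy as np
import stripesim as ss
from stripesim._fft import upsample

system = ss.OpticalSystem(na=1.4, wavelength_nm=520.0, pixel_nm=45.0, shape=(512, 512))
otf = ss.analytic_otf(system)
model = ss.default_illumination(system)          # |k_theta| = 0.8 k_c, m = 0.8

# blind parameter recovery on a filament network (microtubule-like)
truth = ss.make_ground_truth("filaments", (512, 512), seed=1)
stack = ss.simulate_stack(truth, system, model, noise=ss.NoiseModel(photons=500), seed=1)
est = ss.estimate_all(stack, otf)
print("estimated stripe orientations [deg]:", np.round(est.orientations_deg, 2))
print("estimated phases, orientation 0 [deg]:", np.round(np.rad2deg(est.orientation_phases(0)), 2))

# resolution gain on a bead field, reconstructed with the true parameters
beads = ss.make_ground_truth("beads", (512, 512), seed=11, n=30, min_sep=28)
bead_stack = ss.simulate_stack(beads, system, model, noise=None, seed=11)
true_est = ss.IlluminationEstimate(k_theta=model.k_theta, phases_rad=model.phases_rad,
                                   peak_positions=np.zeros((9, 2), int), m=model.m)
res = ss.reconstruct(bead_stack, true_est, otf)
wf = upsample(ss.widefield_reference(beads, system), 2)
y, x = beads.params["positions"][0]
f_wf = ss.bead_fwhm(wf, (2 * y, 2 * x), px=system.pixel_nm / 2)
f_sim = ss.bead_fwhm(res.image, (2 * y, 2 * x), px=system.pixel_nm / 2)
print(f"widefield FWHM: {f_wf:.1f} nm;  SIM FWHM: {f_sim:.1f} nm  (ratio {f_sim / f_wf:.2f})")
```

prints

```
estimated stripe orientations [deg]: [ -0.  60. 120.]
estimated phases, orientation 0 [deg]: [  -0.99  120.07 -120.03]
widefield FWHM: 189.6 nm;  SIM FWHM: 96.6 nm  (ratio 0.51)
```

The estimator recovers the programmed orientations (0°, 60°, 120°) and
120°-stepped phases from shot-noise-limited data, and the reconstructed
bead image is roughly twice as sharp as the diffraction-limited widefield
reference (189.6 nm is the Airy FWHM 0.51·λ/NA at λ = 520 nm, NA = 1.4;
the stripe frequency at 80 % of the cutoff bounds the ideal ratio at
1/1.8 ≈ 0.56, approached here thanks to the Wiener passband flattening).

The same pipeline from the shell:

```
stripesim simulate --kind filaments --shape 256 --noise poisson --seed 7 --out stack.tif
stripesim estimate --stack stack.tif --out params.json
stripesim run --stack stack.tif --out run_out
```

```
wrote stack.tif (9 frames, 256x256)
wrote params.json (orientations [deg]: 0.02, 59.99, 119.99)
wrote run_out/recon.tif (effective cutoff 0.4361 cycles/px, imag residue 2.70e-04)
```

`stripesim patterns --out DIR` writes the nine binary DMD images
(`p{orientation}_{phase}.png`) plus a JSON sidecar with the realised
phases; `stripesim reconstruct` accepts an existing `params.json`, a
measured OTF (32-bit float TIFF via the config) and a `--backend
serial|threads|gpu` switch.

Frame order everywhere is orientation-major: frame `n` is orientation
`n // 3`, phase step `n % 3`.

## Documentation

`docs/methods.md` describes the model, the estimators, all tunable
parameters with their defaults, the synthetic-data generator and known
limitations.
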