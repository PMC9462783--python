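"""Recovery of the experimental illumination parameters from raw frames.

Reconstruction needs, for every orientation, the stripe frequency vector
``k_theta`` to sub-pixel accuracy and, for every frame, the stripe phase
``phi``.  Neither can be taken from the nominal DMD programming: the
optical path and the DMD-to-camera registration shift both, so they are
estimated from the data.

The estimation chain per orientation:

1.  Subtract the orientation mean from each of its 3 frames.  For
    (near-)equispaced phase steps the mean is the widefield image, so the
    residuals contain only the modulated bands — this suppresses the
    sample's own spectrum at the peak location, which would otherwise
    bias both the peak search and the phase.
2.  Coarse peak: the modulation orders are separated with the *nominal*
    equispaced phases (valid up to a global phase factor when the true
    steps are near-equispaced) after Wiener pre-filtering, and the
    first-order band is cross-correlated against the zeroth order; the
    correlation magnitude inside a band-pass annulus peaks at the stripe
    frequency.  Unlike a direct argmax of the frame spectrum, the
    correlation sums coherently over the whole band and is therefore
    robust when the OTF strongly attenuates the peak itself.
3.  Phase of peak: the complex argument of the spectrum at the peak
    (full-quadrant arctangent).  With the field convention
    ``I = I0 (1 + m cos(2 pi k . r + phi))`` the Fourier coefficient at
    ``+k_theta`` carries ``exp(+i phi)``.
4.  Sub-pixel frequency: phase-only correlation between the separated
    first-order band and the zeroth-order band.  In real space the
    normalised cross-spectrum of the two bands is (up to envelope terms)
    a pure complex ramp ``exp(i 2 pi k_theta . r)``, whose frequency is
    read off by a locally up-sampled DFT around the coarse peak
    (0.01-px granularity by default).
5.  Final phases: the frame residuals are demodulated at the *refined*
    frequency (single-coefficient DFT), which removes the bias an
    off-grid frequency induces at the nearest integer bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fft import centered_coords, ft2, ift2, radial_frequency
from .errors import (
    InvalidArgumentError,
    NoPeakError,
    RefinementWarning,
    UndefinedPhaseError,
)
from .forward_sim import RawStack
from .optics import Otf
from .reconstruction import separate_components, separation_matrix

import warnings


@dataclass(frozen=True)
class EstimationConfig:
    """Tunables of the parameter estimator.

    The annulus radii are fractions of the OTF cutoff; defaults bracket
    the usual stripe frequencies (0.3 k_c .. 1.1 k_c).  ``m`` is the
    modulation depth assumed downstream when not estimated from data.
    """

    r_inner_frac: float = 0.3
    r_outer_frac: float = 1.1
    sigma: float = 0.01
    m: float = 0.8
    upsample: int = 100
    search_halfwidth: float = 2.0
    estimate_m: bool = False


@dataclass(frozen=True)
class IlluminationEstimate:
    """Estimated acquisition parameters.

    ``k_theta`` is (3, 2) in cycles/px relative to DC; ``phases_rad`` has
    9 entries wrapped to (-pi, pi]; ``peak_positions`` are the 9 integer
    coarse peaks in grid cycles; ``refined`` flags whether sub-pixel
    refinement succeeded per orientation.
    """

    k_theta: np.ndarray
    phases_rad: np.ndarray
    peak_positions: np.ndarray
    m: float
    m_est: np.ndarray | None = None
    refined: np.ndarray = field(default_factory=lambda: np.ones(3, dtype=bool))

    def orientation_phases(self, index: int) -> np.ndarray:
        return self.phases_rad[3 * index : 3 * index + 3]

    @property
    def orientations_deg(self) -> np.ndarray:
        return np.rad2deg(np.arctan2(self.k_theta[:, 1], self.k_theta[:, 0]))


def bandpass_mask(
    shape: tuple[int, int], r_inner: float, r_outer: float
) -> np.ndarray:
    """Binary annulus ``r_inner <= |k| <= r_outer`` (cycles/px), DC excluded."""
    if not 0 < r_inner < r_outer:
        raise InvalidArgumentError(
            f"need 0 < r_inner < r_outer, got {r_inner}, {r_outer}"
        )
    r = radial_frequency(shape)
    mask = (r >= r_inner) & (r <= r_outer)
    mask[shape[0] // 2, shape[1] // 2] = False
    return mask


def wiener_prefilter(
    spectrum: np.ndarray, otf: np.ndarray | Otf, sigma: float
) -> np.ndarray:
    """Regularised spectral pre-filter conj(OTF) . D / (|OTF| + sigma).

    Suppresses frequencies outside the OTF support (where only noise
    lives) without dividing by zero; ``sigma`` is a small positive
    constant.
    """
    if sigma <= 0:
        raise InvalidArgumentError(f"sigma must be positive, got {sigma}")
    values = otf.values if isinstance(otf, Otf) else np.asarray(otf)
    if values.shape != spectrum.shape:
        raise InvalidArgumentError("spectrum and OTF shapes must agree")
    return np.conj(values) * spectrum / (np.abs(values) + sigma)


def find_modulation_peak(
    frame_spectrum: np.ndarray, mask: np.ndarray, half_plane: bool = True
) -> tuple[int, int]:
    """Integer-precision modulation peak: argmax |spectrum| over the mask.

    Returns (fx, fy) in grid cycles relative to DC.  For Hermitian frame
    spectra the +/- pair is degenerate and the member with positive x
    (ties: positive y) is reported; pass ``half_plane=False`` for
    non-Hermitian inputs such as band cross-correlations, where the peak
    location itself carries the sign.  Raises :class:`NoPeakError` when
    the masked spectrum carries no energy (e.g. unmodulated data) or the
    mask is empty.
    """
    if frame_spectrum.shape != mask.shape:
        raise InvalidArgumentError("spectrum and mask shapes must agree")
    mag = np.abs(frame_spectrum) * mask
    if not mask.any() or float(mag.max()) == 0.0:
        raise NoPeakError("no modulation peak inside the search mask")
    iy, ix = np.unravel_index(int(np.argmax(mag)), mag.shape)
    fy = iy - frame_spectrum.shape[0] // 2
    fx = ix - frame_spectrum.shape[1] // 2
    if half_plane and (fx < 0 or (fx == 0 and fy < 0)):
        fx, fy = -fx, -fy
    return int(fx), int(fy)


def band_cross_correlation(
    frames: np.ndarray, otf: Otf, sigma: float = 0.01
) -> np.ndarray:
    """Cross-correlation spectrum of the first- and zeroth-order bands.

    The three frames of one orientation are Wiener pre-filtered and
    separated with the nominal equispaced phases (0, 120, 240 degrees);
    near-equispaced true steps only contribute a global phase factor,
    which does not move the correlation peak.  The returned centered
    spectrum has its magnitude maximum at the signed stripe frequency
    ``+k_theta``.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] != 3:
        raise InvalidArgumentError("need the 3 frames of one orientation")
    spectra = [wiener_prefilter(ft2(f), otf, sigma) for f in frames]
    nominal = separation_matrix(np.deg2rad([0.0, 120.0, 240.0]), m=1.0)
    band0, band_plus, _ = separate_components(spectra, nominal)
    return ft2(ift2(band_plus) * np.conj(ift2(band0)))


def estimate_phase(frame_spectrum: np.ndarray, peak_coord: tuple[int, int]) -> float:
    """Phase of peak: full-quadrant argument of the spectrum at the peak.

    ``peak_coord`` is (fx, fy) in grid cycles relative to DC.
    """
    h, w = frame_spectrum.shape
    fx, fy = peak_coord
    iy, ix = h // 2 + int(fy), w // 2 + int(fx)
    if not (0 <= iy < h and 0 <= ix < w):
        raise InvalidArgumentError(f"peak {peak_coord} outside the grid {frame_spectrum.shape}")
    value = frame_spectrum[iy, ix]
    if value == 0:
        raise UndefinedPhaseError(f"spectrum is zero at peak {peak_coord}")
    return _wrap_phase(float(np.angle(value)))


def _demodulation_coefficient(image: np.ndarray, k_cyc_px: np.ndarray) -> complex:
    """Single DFT coefficient at an arbitrary (sub-pixel) frequency,
    phase-referenced to the image center."""
    image = np.asarray(image)
    kx, ky = np.asarray(k_cyc_px, dtype=float)
    y, x = centered_coords(image.shape)
    ey = np.exp(-2j * np.pi * ky * y.ravel())
    ex = np.exp(-2j * np.pi * kx * x.ravel())
    return complex(ey @ image @ ex)


def phase_at_frequency(image: np.ndarray, k_cyc_px: np.ndarray) -> float:
    """Phase of the complex demodulation mean at a continuous frequency.

    On a mean-subtracted frame this isolates the ``exp(i phi)`` factor of
    the positive modulation band without integer-bin bias.
    """
    coeff = _demodulation_coefficient(image, k_cyc_px)
    if coeff == 0:
        raise UndefinedPhaseError(f"no signal at frequency {k_cyc_px}")
    return _wrap_phase(float(np.angle(coeff)))


def modulation_amplitude_at(image: np.ndarray, k_cyc_px: np.ndarray) -> float:
    """Magnitude of the demodulation mean (per pixel) at a frequency."""
    image = np.asarray(image)
    return abs(_demodulation_coefficient(image, k_cyc_px)) / image.size


def refine_frequency_subpixel(
    frames: np.ndarray,
    coarse_peak: tuple[int, int],
    otf: Otf,
    sigma: float = 0.01,
    upsample: int = 100,
    search_halfwidth: float = 2.0,
) -> tuple[np.ndarray, bool]:
    """Sub-pixel stripe frequency via phase-only correlation of bands.

    ``frames`` are the 3 frames of one orientation.  The three spectra
    are Wiener pre-filtered, separated into modulation orders with
    phases read at the coarse peak, and the first-order band is
    phase-correlated against the zeroth order: their normalised
    cross-spectrum in real space is a complex ramp at ``k_theta``, whose
    frequency is located on a local grid of pitch ``1 / upsample`` grid
    cycles around the coarse peak.

    Returns ``(k_theta in cycles/px, refined_ok)``; if the refined peak
    strays more than one grid cycle from the coarse peak the coarse value
    is returned with ``refined_ok = False`` and a warning.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] != 3:
        raise InvalidArgumentError("refinement needs the 3 frames of one orientation")
    h, w = frames.shape[1:]
    avg = frames.mean(axis=0)
    residual_spectra = [ft2(f - avg) for f in frames]
    phases = [estimate_phase(s, coarse_peak) for s in residual_spectra]

    # band-flattening weights: both separated bands were attenuated by the
    # same OTF(k), so dividing it out leaves near-unit envelopes whose
    # cross-spectrum phase is an unbiased ramp at k_theta (the raw Eq-14
    # style pre-filter would imprint the OTF shape twice and bias the peak)
    values = otf.values if isinstance(otf, Otf) else np.asarray(otf)
    flatten = values / (values**2 + sigma)
    spectra = [ft2(f) * flatten for f in frames]
    # modulation depth only scales the separated bands; m = 1 is fine here
    matrix = separation_matrix(phases, m=1.0)
    band0, band_plus, _ = separate_components(spectra, matrix)

    cross = ift2(band_plus) * np.conj(ift2(band0))
    # phase-only normalisation, stabilised so empty regions do not inject
    # unit-magnitude noise into the correlation
    norm = np.abs(cross)
    cross = cross / (norm + 1e-3 * norm.max() + np.finfo(float).tiny)

    def local_search(cx: float, cy: float, halfwidth: float, step: float):
        ux = cx + np.arange(-halfwidth, halfwidth + step / 2, step)
        uy = cy + np.arange(-halfwidth, halfwidth + step / 2, step)
        ey = np.exp(-2j * np.pi * np.outer(uy, np.arange(h)) / h)
        ex = np.exp(-2j * np.pi * np.outer(ux, np.arange(w)) / w)
        corr = np.abs(ey @ cross @ ex.T)
        j, i = np.unravel_index(int(np.argmax(corr)), corr.shape)
        edge = i in (0, ux.size - 1) or j in (0, uy.size - 1)
        return ux[i], uy[j], edge

    fx0, fy0 = coarse_peak
    step = 1.0 / upsample
    cx, cy, edge = local_search(float(fx0), float(fy0), search_halfwidth, step)
    if not edge:
        # second pass at 10x finer pitch around the first optimum
        cx, cy, _ = local_search(cx, cy, 2.0 * step, step / 10.0)
    k_grid = np.array([cx, cy])

    if edge or np.max(np.abs(k_grid - np.array(coarse_peak, dtype=float))) > search_halfwidth:
        warnings.warn(
            f"sub-pixel refinement diverged from coarse peak {coarse_peak}; "
            "falling back to the integer estimate",
            RefinementWarning,
            stacklevel=2,
        )
        return np.array([fx0 / w, fy0 / h], dtype=float), False
    return np.array([k_grid[0] / w, k_grid[1] / h]), True


def estimate_all(
    stack: RawStack, otf: Otf, config: EstimationConfig | None = None
) -> IlluminationEstimate:
    """Estimate one frequency vector per orientation and one phase per frame.

    Deterministic given its inputs.  Raises :class:`NoPeakError` naming
    the orientation when a modulation peak cannot be found.
    """
    config = config or EstimationConfig()
    shape = stack.shape
    mask = bandpass_mask(
        shape, config.r_inner_frac * otf.k_c_px, config.r_outer_frac * otf.k_c_px
    )

    k_theta = np.zeros((3, 2))
    phases = np.zeros(9)
    peaks = np.zeros((9, 2), dtype=int)
    refined = np.ones(3, dtype=bool)
    m_est = np.zeros(3)

    for o in range(3):
        frames = stack.orientation(o)
        avg = frames.mean(axis=0)
        residuals = frames - avg
        spectra = [ft2(r) for r in residuals]
        # significance guard: without modulation the frames are identical
        # and the residuals carry only numerical noise
        residual_peak = max(float(np.abs(s).max()) for s in spectra)
        if residual_peak <= 1e-9 * float(np.abs(ft2(avg)).max()):
            raise NoPeakError(
                f"orientation {o}: frames show no modulation (residual energy "
                f"{residual_peak:.3e} is at numerical-noise level)"
            )
        try:
            corr = band_cross_correlation(frames, otf, config.sigma)
            coarse = find_modulation_peak(corr, mask, half_plane=False)
        except NoPeakError as exc:
            raise NoPeakError(f"orientation {o}: {exc}") from exc
        # per-frame integer peaks: limited search near the orientation peak
        local = _disk_mask(shape, coarse, radius=4)
        frame_peaks = [
            find_modulation_peak(s, local, half_plane=False) for s in spectra
        ]
        peaks[3 * o : 3 * o + 3] = frame_peaks
        k_vec, ok = refine_frequency_subpixel(
            frames,
            coarse,
            otf,
            sigma=config.sigma,
            upsample=config.upsample,
            search_halfwidth=config.search_halfwidth,
        )
        k_theta[o] = k_vec
        refined[o] = ok
        for j, res in enumerate(residuals):
            phases[3 * o + j] = phase_at_frequency(res, k_vec)
        if config.estimate_m:
            otf_at_k = float(np.atleast_1d(otf.value_at(k_vec[None, :]))[0])
            dc = float(avg.mean())
            if otf_at_k > 0 and dc > 0:
                amps = [modulation_amplitude_at(res, k_vec) for res in residuals]
                m_est[o] = 2.0 * float(np.mean(amps)) / (dc * otf_at_k)

    return IlluminationEstimate(
        k_theta=k_theta,
        phases_rad=phases,
        peak_positions=peaks,
        m=config.m,
        m_est=m_est if config.estimate_m else None,
        refined=refined,
    )


def _disk_mask(
    shape: tuple[int, int], center_grid: tuple[int, int], radius: int
) -> np.ndarray:
    """Binary disk of ``radius`` grid cycles around a grid-cycle coordinate."""
    h, w = shape
    fy = np.arange(h)[:, None] - (h // 2 + center_grid[1])
    fx = np.arange(w)[None, :] - (w // 2 + center_grid[0])
    return fx**2 + fy**2 <= radius**2


def _wrap_phase(phi: float) -> float:
    """Wrap to (-pi, pi]."""
    wrapped = (phi + np.pi) % (2.0 * np.pi) - np.pi
    return np.pi if wrapped == -np.pi else wrapped
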