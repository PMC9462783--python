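"""Resolution metrics: bead FWHM and spectral support radius.

Super-resolution claims are quantified two ways: in real space by the
full width at half maximum (FWHM) of point-emitter images, and in
frequency space by how far significant spectral energy extends beyond
the widefield cutoff.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from ._fft import radial_frequency
from .errors import InvalidArgumentError


def profile_fwhm(profile: np.ndarray, px: float = 1.0) -> float:
    """FWHM of a single-peaked 1-D profile by cubic interpolation.

    The profile is measured above its boundary baseline; half-maximum
    crossings are located on a 100x-oversampled cubic spline.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 5:
        raise InvalidArgumentError("profile must be 1-D with at least 5 samples")
    baseline = min(profile[0], profile[-1])
    prof = profile - baseline
    x = np.arange(prof.size)
    spline = CubicSpline(x, prof)
    xf = np.linspace(0, prof.size - 1, prof.size * 100)
    yf = spline(xf)
    imax = int(np.argmax(yf))
    half = yf[imax] / 2.0
    if half <= 0:
        raise InvalidArgumentError("profile has no positive peak")
    left = np.nonzero(yf[:imax] < half)[0]
    right = np.nonzero(yf[imax:] < half)[0]
    if left.size == 0 or right.size == 0:
        raise InvalidArgumentError("half-maximum not crossed inside the profile window")
    x_left = np.interp(half, [yf[left[-1]], yf[left[-1] + 1]], [xf[left[-1]], xf[left[-1] + 1]])
    i_r = imax + right[0]
    x_right = np.interp(half, [yf[i_r], yf[i_r - 1]], [xf[i_r], xf[i_r - 1]])
    return float((x_right - x_left) * px)


def bead_fwhm(
    image: np.ndarray,
    center: tuple[int, int],
    px: float = 1.0,
    halfwidth: int = 12,
    refine: int = 3,
) -> float:
    """Mean of the horizontal and vertical FWHM through one bead.

    ``center`` is (row, col); the true maximum is searched within
    ``refine`` px of it first.
    """
    image = np.asarray(image, dtype=float)
    r0, c0 = (int(c) for c in center)
    r_lo, r_hi = max(r0 - refine, 0), min(r0 + refine + 1, image.shape[0])
    c_lo, c_hi = max(c0 - refine, 0), min(c0 + refine + 1, image.shape[1])
    local = image[r_lo:r_hi, c_lo:c_hi]
    dr, dc = np.unravel_index(int(np.argmax(local)), local.shape)
    r, c = r_lo + dr, c_lo + dc
    row = image[r, max(c - halfwidth, 0) : c + halfwidth + 1]
    col = image[max(r - halfwidth, 0) : r + halfwidth + 1, c]
    return 0.5 * (profile_fwhm(row, px) + profile_fwhm(col, px))


def spectral_support_radius(
    spectrum: np.ndarray, level: float = 0.01
) -> float:
    """Largest radius (grid cycles) whose ring still carries energy.

    The ring maximum of |spectrum| is compared against ``level`` times
    the global maximum; radii are binned at 1 grid-cycle resolution.
    """
    if not 0 < level < 1:
        raise InvalidArgumentError("level must be in (0, 1)")
    mag = np.abs(np.asarray(spectrum))
    peak = mag.max()
    if peak == 0:
        return 0.0
    h, w = mag.shape
    r = radial_frequency(mag.shape) * min(h, w)  # grid cycles (square grids)
    bins = np.round(r).astype(int)
    n_bins = bins.max() + 1
    ring_max = np.zeros(n_bins)
    np.maximum.at(ring_max, bins.ravel(), mag.ravel())
    above = np.nonzero(ring_max >= level * peak)[0]
    return float(above.max()) if above.size else 0.0


def nrmse(a: np.ndarray, b: np.ndarray) -> float:
    """Scale-invariant root-mean-square error between two images.

    Both images are shifted and scaled to zero mean / unit variance
    first, so the metric measures structural disagreement only.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError(f"shape mismatch {a.shape} vs {b.shape}")
    az = (a - a.mean()) / (a.std() + np.finfo(float).tiny)
    bz = (b - b.mean()) / (b.std() + np.finfo(float).tiny)
    return float(np.sqrt(np.mean((az - bz) ** 2)))
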