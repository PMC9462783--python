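"""Diffraction-limited incoherent optical model: cutoff, OTF, PSF.

The microscope acts as a low-pass filter: for incoherent fluorescence
detection through a circular pupil of numerical aperture ``NA`` at
emission wavelength ``lambda``, spatial frequencies beyond the cutoff

    k_c = 2 NA / lambda        [cycles per length]

are not transmitted.  We store the cutoff in cycles/length (and
cycles/px via the sample-space pixel size); the angular-frequency
convention ``k_c = 2 pi * 2 NA / lambda`` found in parts of the
literature differs only by the 2 pi factor and is never stored here.

The analytic OTF of the incoherent circular-pupil system is the pupil
autocorrelation

    O(rho) = (2 / pi) * (arccos(rho) - rho * sqrt(1 - rho^2)),   rho = |k| / k_c <= 1

and exactly zero beyond the cutoff.  Real instruments deviate from this
ideal (aberrations, vibration), so a measured 2-D OTF image can be
substituted; the analytic model is what makes synthetic validation with
a sharp, known support possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from ._fft import ft2, ift2, radial_frequency
from .errors import DataQualityWarning, FormatError, InvalidArgumentError, NyquistWarning


def cutoff_frequency(na: float, wavelength_nm: float) -> float:
    """Incoherent cutoff 2 NA / lambda in cycles/nm."""
    if na <= 0 or wavelength_nm <= 0:
        raise InvalidArgumentError("na and wavelength_nm must be positive")
    return 2.0 * na / wavelength_nm


def stripe_period_nm(period_px: float, pixel_nm: float) -> float:
    """Sample-plane stripe period in nm for a period given in pixels."""
    if period_px <= 0 or pixel_nm <= 0:
        raise InvalidArgumentError("period_px and pixel_nm must be positive")
    return period_px * pixel_nm


@dataclass(frozen=True)
class OpticalSystem:
    """Optical configuration of the acquisition.

    Parameters
    ----------
    na : numerical aperture of the objective (dimensionless).
    wavelength_nm : emission wavelength in nm.
    pixel_nm : sample-space pixel size in nm.
    shape : (rows, cols) of the working grid.
    """

    na: float
    wavelength_nm: float
    pixel_nm: float
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.na <= 0 or self.wavelength_nm <= 0 or self.pixel_nm <= 0:
            raise InvalidArgumentError(
                "na, wavelength_nm and pixel_nm must all be positive"
            )
        if len(self.shape) != 2 or min(self.shape) <= 0:
            raise InvalidArgumentError(f"shape must be 2 positive ints, got {self.shape}")
        if self.pixel_nm > 1.0 / (2.0 * self.k_c_nm):
            warnings.warn(
                f"pixel size {self.pixel_nm} nm undersamples the cutoff "
                f"{self.k_c_nm:.3e} cycles/nm (Nyquist limit "
                f"{1.0 / (2.0 * self.k_c_nm):.1f} nm); simulations will alias",
                NyquistWarning,
                stacklevel=3,
            )

    @property
    def k_c_nm(self) -> float:
        """Cutoff frequency in cycles/nm."""
        return cutoff_frequency(self.na, self.wavelength_nm)

    @property
    def k_c_px(self) -> float:
        """Cutoff frequency in cycles/px on the sample grid."""
        return self.k_c_nm * self.pixel_nm

    @property
    def min_period_nm(self) -> float:
        """Smallest resolvable period, lambda / (2 NA)."""
        return self.wavelength_nm / (2.0 * self.na)


@dataclass(frozen=True)
class Otf:
    """A 2-D OTF sampled on the centered frequency grid, DC normalised to 1."""

    values: np.ndarray
    k_c_px: float
    source: str = "analytic"  # "analytic" | "measured"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InvalidArgumentError("OTF values must be 2-D")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def value_at(self, k_cyc_px: np.ndarray) -> np.ndarray:
        """Bilinear OTF lookup at (kx, ky) in cycles/px (0 outside the grid)."""
        from scipy.ndimage import map_coordinates

        k = np.atleast_2d(np.asarray(k_cyc_px, dtype=float))
        h, w = self.values.shape
        col = k[:, 0] * w + w // 2
        row = k[:, 1] * h + h // 2
        out = map_coordinates(
            self.values, np.vstack([row, col]), order=1, mode="constant", cval=0.0
        )
        return out if out.size > 1 else float(out[0])


def analytic_otf(system: OpticalSystem, shape: tuple[int, int] | None = None) -> Otf:
    """Diffraction-limited incoherent OTF of a circular pupil.

    ``shape`` overrides the system grid (used for padded reconstruction
    grids, where the same cycles/px cutoff applies).
    """
    shape = tuple(shape) if shape is not None else tuple(system.shape)
    if min(shape) < 8:
        raise InvalidArgumentError(f"grid too small for an OTF: {shape}")
    rho = radial_frequency(shape) / system.k_c_px
    return Otf(values=_pupil_autocorrelation(rho), k_c_px=system.k_c_px, source="analytic")


def _pupil_autocorrelation(rho: np.ndarray) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    inside = np.clip(rho, 0.0, 1.0)
    vals = (2.0 / np.pi) * (np.arccos(inside) - inside * np.sqrt(1.0 - inside**2))
    vals[rho >= 1.0] = 0.0
    return vals


def load_measured_otf(path: str | Path, k_c_px: float) -> Otf:
    """Load a measured OTF from a 2-D float TIFF.

    The image is renormalised so the central (DC) sample equals 1;
    negative values are clipped to zero with a warning.
    """
    arr = np.asarray(tifffile.imread(str(path)), dtype=float)
    if arr.ndim != 2:
        raise FormatError(f"measured OTF must be a single 2-D image, got ndim={arr.ndim}")
    if not np.any(arr):
        raise FormatError("measured OTF is identically zero")
    if np.any(arr < 0):
        warnings.warn(
            "measured OTF contains negative values; clipping to 0",
            DataQualityWarning,
            stacklevel=2,
        )
        arr = np.clip(arr, 0.0, None)
    dc = arr[arr.shape[0] // 2, arr.shape[1] // 2]
    if dc == 0:
        raise FormatError("measured OTF has zero DC value; cannot normalise")
    return Otf(values=arr / dc, k_c_px=k_c_px, source="measured")


def psf_from_otf(otf: Otf) -> np.ndarray:
    """Real-space PSF: centered inverse transform of the OTF, normalised to sum 1."""
    psf = np.real(ift2(otf.values))
    total = psf.sum()
    if total == 0:
        raise InvalidArgumentError("OTF integrates to zero; PSF undefined")
    return psf / total


def otf_from_psf(psf: np.ndarray, k_c_px: float, source: str = "measured") -> Otf:
    """Inverse of :func:`psf_from_otf` (real part, DC-normalised)."""
    spec = np.real(ft2(np.asarray(psf, dtype=float)))
    h, w = spec.shape
    return Otf(values=spec / spec[h // 2, w // 2], k_c_px=k_c_px, source=source)
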