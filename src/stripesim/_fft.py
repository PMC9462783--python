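"""Centered 2-D FFT helpers.

All user-facing spectra in this package have DC at the geometric center
(row ``H // 2``, column ``W // 2``); the corner-DC layout exists only
transiently inside these helpers.  Frequencies are expressed either in
cycles/px (``fftfreq`` units) or in grid cycles (cycles per field of view,
i.e. centered array-index offsets from DC).

The transforms are *symmetric*: the real-space origin sits at pixel
(H // 2, W // 2) as well, so spectral phases are referenced to the image
center (the optical axis), not the top-left corner.  This keeps phase
estimates decoupled from small frequency errors, which would otherwise
leak into the phase through the half-diagonal lever arm to the corner.
"""

from __future__ import annotations

import numpy as np


def ft2(image: np.ndarray) -> np.ndarray:
    """Forward 2-D FFT, center-referenced in both domains."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image)))


def ift2(spectrum: np.ndarray) -> np.ndarray:
    """Inverse of :func:`ft2`."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(spectrum)))


def centered_coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Real-space coordinates (y, x) in px relative to the image center."""
    y = (np.arange(shape[0]) - shape[0] // 2)[:, None]
    x = (np.arange(shape[1]) - shape[1] // 2)[None, :]
    return y, x


def freq_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Centered frequency coordinates in cycles/px.

    Returns ``(fy, fx)`` broadcastable over an array of ``shape``.
    """
    fy = np.fft.fftshift(np.fft.fftfreq(shape[0]))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(shape[1]))[None, :]
    return fy, fx


def radial_frequency(shape: tuple[int, int]) -> np.ndarray:
    """Radial frequency magnitude |k| in cycles/px on the centered grid."""
    fy, fx = freq_grids(shape)
    return np.hypot(fy, fx)


def pad_spectrum(spectrum: np.ndarray, factor: int) -> np.ndarray:
    """Embed a centered spectrum in a ``factor``-times larger zero grid.

    Grid-cycle coordinates (index offsets from DC) are preserved, so the
    padded spectrum describes the same field of view sampled ``factor``
    times more finely.
    """
    h, w = spectrum.shape
    hp, wp = h * factor, w * factor
    out = np.zeros((hp, wp), dtype=spectrum.dtype)
    y0 = hp // 2 - h // 2
    x0 = wp // 2 - w // 2
    out[y0 : y0 + h, x0 : x0 + w] = spectrum
    return out


def upsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Fourier-interpolate an image by zero-padding its spectrum.

    A feature at pixel ``r`` lands at pixel ``factor * r``.  Total
    intensity is preserved up to the interpolation itself.
    """
    spec = ft2(image)
    up = ift2(pad_spectrum(spec, factor)) * factor**2
    return np.real(up)
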