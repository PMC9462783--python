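"""Binary stripe patterns for a digital micromirror device (DMD).

A DMD is a binary projector: each micromirror is either *on* or *off*.
Sinusoidal stripe illumination for SIM is therefore programmed as a binary
square wave whose fundamental harmonic, after blurring by the projection
optics, becomes the sinusoid of the illumination model.  Lateral phase
stepping is realised by shifting the whole pattern along the stripe normal
by an integer number of mirrors; a phase step of 2pi/3 is an integer shift
only when the period is a multiple of 3 px, and a 50 % duty cycle
additionally needs an even period, which makes 6 px (3 on / 3 off, shift
2 px per step) the smallest exact geometry.

Coordinate convention: ``x`` is the column index, ``y`` the row index,
origin at the top-left, row-major storage.  The stripe normal for
orientation ``theta`` (degrees) is ``(cos theta, sin theta)`` in (x, y).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .errors import InvalidArgumentError, NonRepresentablePhaseWarning

TWO_PI = 2.0 * np.pi

#: Default acquisition geometry: three stripe orientations, three phase
#: steps of 120 degrees each, nine patterns total.
DEFAULT_ORIENTATIONS_DEG = (0.0, 60.0, 120.0)
DEFAULT_PHASES_RAD = (0.0, TWO_PI / 3.0, 2.0 * TWO_PI / 3.0)


@dataclass(frozen=True)
class DmdPattern:
    """A binary stripe image together with the parameters that define it.

    ``phase_rad`` is the requested phase; ``realized_phase_rad`` is the
    phase actually encoded after rounding the shift to a whole mirror.
    They agree whenever the requested phase corresponds to an integer
    pixel shift of the period.
    """

    pixels: np.ndarray
    period_px: int
    orientation_deg: float
    phase_rad: float
    duty_on_px: int
    realized_phase_rad: float = field(default=float("nan"))
    exact: bool = True

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InvalidArgumentError("pattern pixels must be a 2-D array")
        if not np.isin(px, (0, 1)).all():
            raise InvalidArgumentError("pattern pixels must be strictly binary")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        if np.isnan(self.realized_phase_rad):
            object.__setattr__(self, "realized_phase_rad", float(self.phase_rad))

    @property
    def on_fraction(self) -> float:
        return float(self.pixels.mean())

    def save(self, path: str | Path) -> None:
        """Write the pattern as a 1-bit PNG (any DMD loader format that
        PIL supports works; PNG is the default)."""
        Image.fromarray(self.pixels.astype(bool)).save(Path(path))

    @staticmethod
    def load_pixels(path: str | Path) -> np.ndarray:
        """Read a binary pattern image back as a uint8 0/1 matrix."""
        arr = np.asarray(Image.open(Path(path)).convert("1"))
        return arr.astype(np.uint8)


def phase_representable(period_px: int, phase_rad: float, tol: float = 1e-9) -> bool:
    """True if ``phase_rad`` is an exact integer pixel shift at this period."""
    if period_px <= 0:
        raise InvalidArgumentError(f"period_px must be positive, got {period_px}")
    shift = period_px * phase_rad / TWO_PI
    return bool(abs(shift - round(shift)) <= tol)


def pixel_shift_for_phase(period_px: int, phase_rad: float) -> int:
    """Pixel shift along the stripe normal that realises a phase step.

    A shift of ``s`` pixels of a pattern with period ``P`` advances the
    stripe phase by ``2 pi s / P``; inverting gives
    ``s = round(P * phase / 2 pi)``.  The canonical SIM geometry —
    period 6 px, phase step 120 degrees — gives a shift of 2 px.
    A warning is issued when the requested phase is not exactly
    representable (the rounded shift is still returned).
    """
    if period_px < 2:
        raise InvalidArgumentError(f"period_px must be >= 2, got {period_px}")
    exact_shift = period_px * phase_rad / TWO_PI
    shift = int(round(exact_shift))
    if abs(exact_shift - shift) > 1e-9:
        warnings.warn(
            f"phase {phase_rad:.6g} rad is not an integer pixel shift at "
            f"period {period_px} px (exact shift {exact_shift:.4f}); rounded to {shift}",
            NonRepresentablePhaseWarning,
            stacklevel=2,
        )
    return shift


def generate_stripe_pattern(
    width: int,
    height: int,
    period_px: int,
    orientation_deg: float = 0.0,
    phase_rad: float = 0.0,
    duty_on_px: int | None = None,
) -> DmdPattern:
    """Rasterize one binary stripe pattern.

    A pixel (x, y) is *on* iff the fractional stripe coordinate
    ``frac((x cos t + y sin t) / P - phi / 2 pi)`` is below
    ``duty_on_px / P``.  Non-representable phases are rounded to the
    nearest whole-pixel shift (with a warning); the realised phase is
    recorded on the returned pattern so downstream code never has to
    trust the nominal value.
    """
    if width <= 0 or height <= 0:
        raise InvalidArgumentError("width and height must be positive")
    if period_px < 2:
        raise InvalidArgumentError(f"period_px must be >= 2, got {period_px}")
    if duty_on_px is None:
        duty_on_px = period_px // 2
    if not 1 <= duty_on_px < period_px:
        raise InvalidArgumentError(
            f"duty_on_px must satisfy 1 <= duty < period ({duty_on_px} vs {period_px})"
        )

    shift = pixel_shift_for_phase(period_px, phase_rad)
    realized_phase = TWO_PI * shift / period_px
    exact = phase_representable(period_px, phase_rad)

    theta = np.deg2rad(orientation_deg)
    x = np.arange(width)[None, :]
    y = np.arange(height)[:, None]
    coord = x * np.cos(theta) + y * np.sin(theta) - shift
    # tiny epsilon guards the on/off threshold against float round-off at
    # exact stripe boundaries (cos/sin of oblique angles are irrational)
    pos = np.mod(coord + 1e-9, period_px)
    pixels = (pos < duty_on_px).astype(np.uint8)
    return DmdPattern(
        pixels=pixels,
        period_px=period_px,
        orientation_deg=float(orientation_deg),
        phase_rad=float(phase_rad),
        duty_on_px=int(duty_on_px),
        realized_phase_rad=float(realized_phase),
        exact=exact,
    )


def pattern_set(
    width: int,
    height: int,
    orientations_deg: Sequence[float] = DEFAULT_ORIENTATIONS_DEG,
    phases_rad: Sequence[float] = DEFAULT_PHASES_RAD,
    period_px: int = 6,
    duty_on_px: int = 3,
) -> list[DmdPattern]:
    """The ordered 9-pattern acquisition set.

    Ordering is orientation-major, phase-minor: pattern index
    ``n = 3 * orientation_index + phase_index``.  This ordering is the
    single frame-order convention used throughout the package.
    """
    if len(orientations_deg) != 3:
        raise InvalidArgumentError(
            f"expected 3 orientations, got {len(orientations_deg)}"
        )
    if len(phases_rad) != 3:
        raise InvalidArgumentError(f"expected 3 phases, got {len(phases_rad)}")
    return [
        generate_stripe_pattern(
            width, height, period_px, theta, phi, duty_on_px
        )
        for theta in orientations_deg
        for phi in phases_rad
    ]


def save_pattern_set(patterns: Sequence[DmdPattern], out_dir: str | Path) -> Path:
    """Write nine patterns as ``p{orient}_{phase}.png`` plus a JSON sidecar
    recording the realised phases.  Returns the sidecar path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = []
    for n, pat in enumerate(patterns):
        o, p = divmod(n, 3)
        pat.save(out / f"p{o}_{p}.png")
        meta.append(
            {
                "index": n,
                "file": f"p{o}_{p}.png",
                "orientation_deg": pat.orientation_deg,
                "period_px": pat.period_px,
                "duty_on_px": pat.duty_on_px,
                "requested_phase_rad": pat.phase_rad,
                "realized_phase_rad": pat.realized_phase_rad,
                "exact": pat.exact,
            }
        )
    sidecar = out / "patterns.json"
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def fundamental_phase(profile: np.ndarray, period_px: int) -> float:
    """Phase angle of the fundamental Fourier coefficient of a 1-D profile.

    Used as an independent check of the shift/phase arithmetic: rolling a
    periodic profile by ``s`` pixels changes this angle by exactly
    ``-2 pi s / period``.
    """
    profile = np.asarray(profile, dtype=float).ravel()
    n = profile.size
    coeff = np.sum(profile * np.exp(-2j * np.pi * np.arange(n) / period_px))
    if coeff == 0:
        raise InvalidArgumentError("profile has no fundamental harmonic")
    return float(np.angle(coeff))
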