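"""Forward image-formation simulator for stripe-illumination SIM.

Implements the standard incoherent SIM imaging model.  The sample
fluorophore density ``S(r)`` is excited by a sinusoidal stripe field

    I(r) = I0 * (1 + m * cos(2 pi k_theta . r + phi)),

the emission ``E(r) = I(r) * S(r)`` is blurred by the microscope PSF
(circular convolution via the OTF), and the detector adds shot noise
(Poisson, parameterised by the peak photon budget) and Gaussian read
noise.  A full acquisition is 9 frames: 3 stripe orientations times 3
phase steps, orientation-major.

The illumination is evaluated in real space, so ``k_theta`` may be any
continuous frequency in cycles/px — it need not be a grid frequency.
That is deliberate: sub-pixel frequency estimation downstream is only a
meaningful test if the simulated frequency can fall between grid points.

The stack records the *true* illumination parameters in its metadata so
estimators can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._fft import centered_coords, ft2, ift2
from .errors import InvalidArgumentError
from .optics import OpticalSystem, Otf, analytic_otf

#: Simulation defaults: illumination frequency at 80 % of the OTF cutoff,
#: 80 % modulation contrast, 500 detected photons per unit intensity and
#: 2 DN rms read noise.
DEFAULT_KTHETA_FRAC = 0.8
DEFAULT_MODULATION = 0.8
DEFAULT_PHOTONS = 500.0
DEFAULT_READ_NOISE_DN = 2.0


@dataclass(frozen=True)
class GroundTruth:
    """A known fluorophore density used as simulation input."""

    values: np.ndarray
    kind: str
    seed: int | None = None
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise InvalidArgumentError("ground truth must be finite and non-negative")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class IlluminationModel:
    """Per-orientation stripe frequency vectors and per-frame phases.

    ``k_theta`` is a (3, 2) array of (kx, ky) in cycles/px; ``phases_rad``
    has one entry per frame (9, orientation-major); ``m`` in [0, 1] is the
    modulation depth and ``i0 > 0`` the mean intensity.
    """

    k_theta: np.ndarray
    phases_rad: np.ndarray
    m: float = DEFAULT_MODULATION
    i0: float = 1.0

    def __post_init__(self) -> None:
        k = np.asarray(self.k_theta, dtype=float)
        p = np.asarray(self.phases_rad, dtype=float)
        if k.shape != (3, 2):
            raise InvalidArgumentError(f"k_theta must be (3, 2), got {k.shape}")
        if p.shape != (9,):
            raise InvalidArgumentError(f"phases_rad must have 9 entries, got {p.shape}")
        if not 0.0 <= self.m <= 1.0:
            raise InvalidArgumentError(f"modulation depth m must be in [0, 1], got {self.m}")
        if self.i0 <= 0:
            raise InvalidArgumentError(f"i0 must be positive, got {self.i0}")
        object.__setattr__(self, "k_theta", k)
        object.__setattr__(self, "phases_rad", p)

    @property
    def orientations_deg(self) -> np.ndarray:
        return np.rad2deg(np.arctan2(self.k_theta[:, 1], self.k_theta[:, 0]))


def default_illumination(
    system: OpticalSystem,
    ktheta_frac: float = DEFAULT_KTHETA_FRAC,
    m: float = DEFAULT_MODULATION,
    i0: float = 1.0,
    orientations_deg: tuple[float, float, float] = (0.0, 60.0, 120.0),
    phase_steps_rad: tuple[float, float, float] = (0.0, 2 * np.pi / 3, 4 * np.pi / 3),
) -> IlluminationModel:
    """Standard acquisition geometry: |k_theta| = ktheta_frac * k_c at three
    orientations, equispaced 120-degree phase steps at each orientation."""
    mag = ktheta_frac * system.k_c_px
    theta = np.deg2rad(np.asarray(orientations_deg, dtype=float))
    k = mag * np.column_stack([np.cos(theta), np.sin(theta)])
    phases = np.tile(np.asarray(phase_steps_rad, dtype=float), 3)
    return IlluminationModel(k_theta=k, phases_rad=phases, m=m, i0=i0)


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: Poisson shot noise plus Gaussian read noise.

    ``photons`` is the expected photon count for unit noiseless intensity;
    ``read_noise_dn`` is the read-noise rms in detector numbers, with one
    DN defined as one photon (so its contribution in normalised intensity
    units is ``read_noise_dn / photons``).
    """

    poisson: bool = True
    photons: float = DEFAULT_PHOTONS
    read_noise_dn: float = DEFAULT_READ_NOISE_DN

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(poisson=False, photons=DEFAULT_PHOTONS, read_noise_dn=0.0)

    @property
    def enabled(self) -> bool:
        return self.poisson or self.read_noise_dn > 0


@dataclass(frozen=True)
class RawStack:
    """Nine raw frames (orientation-major) plus acquisition metadata."""

    frames: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[0] != 9:
            raise InvalidArgumentError(
                f"a raw stack holds exactly 9 same-shape frames, got shape {f.shape}"
            )
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            raise InvalidArgumentError("frames must be finite and non-negative")
        object.__setattr__(self, "frames", f)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def orientation(self, index: int) -> np.ndarray:
        """The 3 frames of one orientation, phase-minor order."""
        if not 0 <= index < 3:
            raise InvalidArgumentError(f"orientation index must be 0..2, got {index}")
        return self.frames[3 * index : 3 * index + 3]


# ---------------------------------------------------------------------------
# ground-truth targets


def make_ground_truth(
    kind: str, shape: tuple[int, int] = (512, 512), seed: int = 0, **kind_params: Any
) -> GroundTruth:
    """Deterministic synthetic targets.

    kinds
    -----
    ``beads``     isolated single-pixel point emitters (``n``, ``min_sep``,
                  ``margin``); positions are recorded in ``params``.
    ``spokes``    a Siemens-star radial target (``n_spokes``) — dense
                  orientation/frequency coverage.
    ``filaments`` random-walk curves of 1-px width (``n``, ``steps``) —
                  a microtubule-like line network.
    ``custom``    caller-provided ``values``.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 64:
        raise InvalidArgumentError(f"ground-truth grid must be at least 64x64, got {shape}")
    rng = np.random.default_rng(seed)
    if kind == "beads":
        return _beads(shape, seed, rng, **kind_params)
    if kind == "spokes":
        return _spokes(shape, seed, **kind_params)
    if kind == "filaments":
        return _filaments(shape, seed, rng, **kind_params)
    if kind == "custom":
        values = kind_params.pop("values", None)
        if values is None:
            raise InvalidArgumentError("kind 'custom' requires a 'values' array")
        return GroundTruth(values=values, kind="custom", seed=seed, params=kind_params)
    raise InvalidArgumentError(f"unknown ground-truth kind {kind!r}")


def _beads(shape, seed, rng, n: int = 40, min_sep: int = 14, margin: int = 10):
    h, w = shape
    positions: list[tuple[int, int]] = []
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > 100_000:
            raise InvalidArgumentError(
                f"cannot place {n} beads with min_sep={min_sep} on a {shape} grid"
            )
        y = int(rng.integers(margin, h - margin))
        x = int(rng.integers(margin, w - margin))
        if all((y - py) ** 2 + (x - px) ** 2 >= min_sep**2 for py, px in positions):
            positions.append((y, x))
    values = np.zeros(shape)
    for y, x in positions:
        values[y, x] = 1.0
    return GroundTruth(
        values=values,
        kind="beads",
        seed=seed,
        params={"n": n, "min_sep": min_sep, "positions": positions},
    )


def _spokes(shape, seed, n_spokes: int = 24, hole_px: float = 3.0):
    h, w = shape
    y = np.arange(h)[:, None] - h / 2
    x = np.arange(w)[None, :] - w / 2
    r = np.hypot(x, y)
    ang = np.arctan2(y, x)
    values = 0.5 * (1.0 + np.cos(n_spokes * ang))
    values[(r < hole_px) | (r > 0.45 * min(shape))] = 0.0
    return GroundTruth(values=values, kind="spokes", seed=seed, params={"n_spokes": n_spokes})


def _filaments(shape, seed, rng, n: int = 12, steps: int | None = None, wobble: float = 0.15):
    h, w = shape
    steps = steps if steps is not None else int(0.8 * min(shape))
    values = np.zeros(shape)
    for _ in range(n):
        y, x = rng.uniform(0, h), rng.uniform(0, w)
        direction = rng.uniform(0, 2 * np.pi)
        for _ in range(steps):
            direction += rng.normal(0.0, wobble)
            y += np.sin(direction)
            x += np.cos(direction)
            iy, ix = int(round(y)) % h, int(round(x)) % w
            values[iy, ix] = 1.0
    return GroundTruth(values=values, kind="filaments", seed=seed, params={"n": n, "steps": steps})


# ---------------------------------------------------------------------------
# image formation


def illumination_field(
    model: IlluminationModel, frame_index: int, shape: tuple[int, int]
) -> np.ndarray:
    """The sinusoidal excitation intensity for one frame, evaluated in real
    space (exact for off-grid frequencies)."""
    if not 0 <= frame_index < 9:
        raise InvalidArgumentError(f"frame_index must be 0..8, got {frame_index}")
    kx, ky = model.k_theta[frame_index // 3]
    phi = model.phases_rad[frame_index]
    y, x = centered_coords(shape)
    return model.i0 * (1.0 + model.m * np.cos(2.0 * np.pi * (kx * x + ky * y) + phi))


def _blur(image: np.ndarray, otf: Otf) -> np.ndarray:
    """Circular convolution with the PSF, applied as an OTF product."""
    return np.real(ift2(ft2(image) * otf.values))


def simulate_frame(
    truth: GroundTruth,
    system: OpticalSystem,
    model: IlluminationModel,
    frame_index: int,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    otf: Otf | None = None,
) -> np.ndarray:
    """One raw frame: modulate, blur, then (optionally) add detector noise."""
    if truth.shape != tuple(system.shape):
        raise InvalidArgumentError(
            f"truth shape {truth.shape} does not match system grid {system.shape}"
        )
    if otf is None:
        otf = analytic_otf(system)
    field_ = illumination_field(model, frame_index, truth.shape)
    clean = np.clip(_blur(field_ * truth.values, otf), 0.0, None)
    if noise is None or not noise.enabled:
        return clean
    if rng is None:
        rng = np.random.default_rng()
    out = clean
    if noise.poisson:
        if noise.photons <= 0:
            raise InvalidArgumentError("photon budget must be positive for shot noise")
        out = rng.poisson(clean * noise.photons).astype(float) / noise.photons
    if noise.read_noise_dn > 0:
        out = out + rng.normal(0.0, noise.read_noise_dn / noise.photons, size=out.shape)
    return np.clip(out, 0.0, None)


def simulate_stack(
    truth: GroundTruth,
    system: OpticalSystem,
    model: IlluminationModel,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> RawStack:
    """The full 9-frame acquisition.  ``seed`` controls all randomness; the
    metadata records the true illumination parameters for validation."""
    otf = analytic_otf(system)
    rng = np.random.default_rng(seed)
    frames = np.stack(
        [
            simulate_frame(truth, system, model, n, noise=noise, rng=rng, otf=otf)
            for n in range(9)
        ]
    )
    meta = {
        "system": {
            "na": system.na,
            "wavelength_nm": system.wavelength_nm,
            "pixel_nm": system.pixel_nm,
        },
        "illumination": {
            "k_theta": model.k_theta.tolist(),
            "phases_rad": model.phases_rad.tolist(),
            "m": model.m,
            "i0": model.i0,
        },
        "noise": {
            "poisson": bool(noise.poisson) if noise else False,
            "photons": float(noise.photons) if noise else None,
            "read_noise_dn": float(noise.read_noise_dn) if noise else 0.0,
        },
        "seed": seed,
        "truth_kind": truth.kind,
    }
    return RawStack(frames=frames, meta=meta)


def widefield_reference(
    truth: GroundTruth,
    system: OpticalSystem,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Uniform-illumination (all mirrors on) reference: the m = 0 frame."""
    flat = IlluminationModel(
        k_theta=np.zeros((3, 2)), phases_rad=np.zeros(9), m=0.0, i0=1.0
    )
    rng = np.random.default_rng(seed)
    return simulate_frame(truth, system, flat, 0, noise=noise, rng=rng)
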