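"""Raw-stack I/O and the end-to-end pipeline runner.

Stacks travel as 32-bit float multi-page TIFFs (page n = frame n,
orientation-major) or as directories of nine single-page TIFFs sorted
lexicographically.  Integer inputs are scaled to [0, 1] by their dtype
range.  A JSON sidecar next to the stack (same stem, ``.json``) carries
acquisition metadata when available, including the simulator's ground
truth parameters.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

import stripesim

from .config import PipelineConfig
from .errors import FormatError
from .forward_sim import RawStack
from .optics import OpticalSystem, analytic_otf, load_measured_otf
from .parameter_estimation import EstimationConfig, IlluminationEstimate, estimate_all
from .preprocessing import preprocess_stack
from .reconstruction import ReconstructionResult, reconstruct

logger = logging.getLogger("stripesim")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_stack(path: str | Path) -> RawStack:
    """Read a 9-frame stack from a multi-page TIFF or a directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if len(files) != 9:
            raise FormatError(
                f"directory {path} holds {len(files)} TIFF files; expected 9"
            )
        frames = [np.asarray(tifffile.imread(str(f))) for f in files]
        meta_path = path / "stack.json"
    else:
        data = np.asarray(tifffile.imread(str(path)))
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3 or data.shape[0] != 9:
            raise FormatError(
                f"{path} holds {data.shape[0] if data.ndim == 3 else 1} pages; expected 9"
            )
        frames = list(data)
        meta_path = _sidecar_path(path)

    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"frames have mixed shapes: {sorted(shapes)}")
    scaled = np.stack([_to_unit_float(f) for f in frames])

    meta: dict[str, Any] = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    return RawStack(frames=scaled, meta=meta)


def _to_unit_float(frame: np.ndarray) -> np.ndarray:
    if frame.ndim != 2:
        raise FormatError(f"each frame must be 2-D, got shape {frame.shape}")
    if frame.dtype == np.uint8:
        return frame.astype(float) / 255.0
    if frame.dtype == np.uint16:
        return frame.astype(float) / 65535.0
    if np.issubdtype(frame.dtype, np.floating):
        return frame.astype(float)
    raise FormatError(f"unsupported frame dtype {frame.dtype}")


def write_stack(stack: RawStack, path: str | Path) -> None:
    """Write a stack as a 32-bit float multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    _check_finite(stack.frames)
    tifffile.imwrite(str(path), stack.frames.astype(np.float32))
    if stack.meta:
        _sidecar_path(path).write_text(json.dumps(stack.meta, indent=2, default=_default))


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a single 2-D image as 32-bit float TIFF."""
    image = np.asarray(image)
    _check_finite(image)
    tifffile.imwrite(str(Path(path)), image.astype(np.float32))


def _check_finite(data: np.ndarray) -> None:
    if not np.all(np.isfinite(data)):
        raise FormatError("refusing to write non-finite (NaN/inf) image data")


def _default(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def estimate_to_dict(estimate: IlluminationEstimate) -> dict[str, Any]:
    """JSON-ready parameter record, one entry per orientation."""
    return {
        "orientations": [
            {
                "k": estimate.k_theta[o].tolist(),
                "phases_deg": np.rad2deg(estimate.orientation_phases(o)).tolist(),
                "peak_px": estimate.peak_positions[3 * o : 3 * o + 3].tolist(),
                "refined": bool(estimate.refined[o]),
            }
            for o in range(3)
        ],
        "m": estimate.m,
        "m_est": None if estimate.m_est is None else estimate.m_est.tolist(),
    }


def run_pipeline(
    config: PipelineConfig, stack_path: str | Path, out_dir: str | Path
) -> ReconstructionResult:
    """preprocess -> estimate -> reconstruct, with artifacts on disk.

    Writes ``recon.tif``, ``widefield.tif`` (mean of the nine frames —
    the uniform-illumination equivalent), ``params.json``, and a
    ``manifest.json`` recording config hash, seed, package version and
    per-stage durations.  Deterministic given the config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", name)

            def __exit__(self_, *exc):
                timings[name] = round(time.perf_counter() - self_.t0, 4)
                logger.info("stage %s: %.3fs", name, timings[name])

        return _Timer()

    with stage("read"):
        stack = read_stack(stack_path)
    if config.preprocess.enabled:
        with stage("preprocess"):
            stack = preprocess_stack(
                stack,
                reference_index=config.preprocess.reference_index,
                window=config.preprocess.median_window,
            )
    system = OpticalSystem(
        na=config.optics.na,
        wavelength_nm=config.optics.wavelength_nm,
        pixel_nm=config.optics.pixel_nm,
        shape=stack.shape,
    )
    otf = (
        load_measured_otf(config.optics.otf_path, system.k_c_px)
        if config.optics.otf_path
        else analytic_otf(system)
    )
    with stage("estimate"):
        est_cfg = EstimationConfig(
            r_inner_frac=config.estimation.r_inner_frac,
            r_outer_frac=config.estimation.r_outer_frac,
            sigma=config.estimation.sigma,
            m=config.illumination.m,
            upsample=config.estimation.upsample,
            estimate_m=config.estimation.estimate_m,
        )
        estimate = estimate_all(stack, otf, est_cfg)
    with stage("reconstruct"):
        result = reconstruct(
            stack, estimate, otf, config.reconstruction, backend=config.backend
        )

    with stage("write"):
        write_image(result.image, out / "recon.tif")
        write_image(stack.frames.mean(axis=0), out / "widefield.tif")
        (out / "params.json").write_text(
            json.dumps(estimate_to_dict(estimate), indent=2)
        )
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stack": str(stack_path),
            "stripesim_version": stripesim.__version__,
            "numpy_version": np.__version__,
            "timings_s": timings,
            "effective_cutoff_cyc_px": result.effective_cutoff_cyc_px,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_default))
    return result
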