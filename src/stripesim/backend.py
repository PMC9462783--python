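"""Swappable element-wise array execution.

The reconstruction pipeline is dominated by element-wise complex
arithmetic on full-frame matrices (phase ramps, conjugate products,
Wiener numerator/denominator terms).  On a GPU each such operation maps
onto a grid of thread blocks, every thread owning one matrix element;
the same decomposition also describes a tiled multi-threaded CPU run,
and degenerates to a single whole-array operation on a serial CPU.

This module captures that decomposition as a *backend contract*: a
registry of named element-wise operations plus interchangeable executors
(serial, threaded, optionally GPU via CuPy).  All backends must produce
identical results; the launch-geometry arithmetic (blocks = ceil(size /
block_dim) per axis, overhang threads masked) is exposed so the tiling
itself is testable.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Any, Callable

import numpy as np

from .errors import InvalidArgumentError, NotRegisteredError

#: Default thread-block shape (threads per block along x and y).
DEFAULT_BLOCK_DIM = 32


@dataclass(frozen=True)
class LaunchGeometry:
    """Block/thread decomposition of a 2-D array of size (size_x, size_y)."""

    grid_dims: tuple[int, int]  # (blocks_x, blocks_y)
    block_dims: tuple[int, int]  # (threads_x, threads_y)

    @property
    def total_threads(self) -> int:
        return (
            self.grid_dims[0]
            * self.grid_dims[1]
            * self.block_dims[0]
            * self.block_dims[1]
        )


def launch_geometry(
    size_x: int, size_y: int, dim_x: int = DEFAULT_BLOCK_DIM, dim_y: int = DEFAULT_BLOCK_DIM
) -> LaunchGeometry:
    """Blocks per axis = ceil(size / dim); overhang threads are masked.

    With dim = 32 a 1024 x 1024 image maps to a 32 x 32 block grid with
    no overhang.
    """
    if min(size_x, size_y, dim_x, dim_y) <= 0:
        raise InvalidArgumentError("sizes and block dims must all be positive")
    grid = (math.ceil(size_x / dim_x), math.ceil(size_y / dim_y))
    return LaunchGeometry(grid_dims=grid, block_dims=(dim_x, dim_y))


# ---------------------------------------------------------------------------
# operation registry — one entry per element-wise kernel of the pipeline

OPS: dict[str, Callable[..., np.ndarray]] = {
    "add": lambda a, b: a + b,
    "multiply": lambda a, b: a * b,
    "conjugate_multiply": lambda a, b: np.conj(a) * b,
    "magnitude": lambda a: np.abs(a),
    # complex exponential ramp used by the Fourier shift theorem
    "exp_ramp": lambda phase: np.exp(1j * phase),
    # regularised spectral pre-filter: conj(OTF) . D / (|OTF| + sigma)
    "wiener_ratio": lambda spec, otf, sigma: np.conj(otf) * spec / (np.abs(otf) + sigma),
    # per-band terms of the generalized-Wiener fusion
    "wiener_numerator_term": lambda otf, band: np.conj(otf) * band,
    "wiener_denominator_term": lambda otf: np.abs(otf) ** 2,
}


class Backend:
    """Executes registered element-wise operations."""

    name = "abstract"

    def elementwise(self, op_name: str, *operands: Any) -> np.ndarray:
        raise NotImplementedError

    @staticmethod
    def _op(op_name: str) -> Callable[..., np.ndarray]:
        try:
            return OPS[op_name]
        except KeyError:
            raise NotRegisteredError(
                f"element-wise operation {op_name!r} is not registered "
                f"(known: {sorted(OPS)})"
            ) from None


class SerialBackend(Backend):
    """Whole-array numpy execution; the reference implementation."""

    name = "serial"

    def elementwise(self, op_name: str, *operands: Any) -> np.ndarray:
        return self._op(op_name)(*operands)


class ThreadsBackend(Backend):
    """Tiled multi-threaded execution.

    The array is decomposed with :func:`launch_geometry`; each task
    computes one row of blocks and writes its disjoint output slice.
    Tiles see identical numpy operations, so results match the serial
    backend bit-for-bit regardless of the tiling.
    """

    name = "threads"

    def __init__(self, workers: int | None = None, block_dim: int = DEFAULT_BLOCK_DIM):
        self.workers = workers
        self.block_dim = block_dim

    def elementwise(self, op_name: str, *operands: Any) -> np.ndarray:
        fn = self._op(op_name)
        arrays = [op for op in operands if isinstance(op, np.ndarray) and op.ndim == 2]
        if not arrays:
            return fn(*operands)
        rows, cols = arrays[0].shape
        geom = launch_geometry(cols, rows, self.block_dim, self.block_dim)
        dim = self.block_dim

        def tile_args(y0: int, y1: int, x0: int, x1: int) -> list[Any]:
            return [
                op[y0:y1, x0:x1]
                if isinstance(op, np.ndarray) and op.ndim == 2
                else op
                for op in operands
            ]

        first = fn(*tile_args(0, min(dim, rows), 0, min(dim, cols)))
        out = np.empty((rows, cols), dtype=first.dtype)
        out[: first.shape[0], : first.shape[1]] = first

        def run_block_row(by: int) -> None:
            y0, y1 = by * dim, min((by + 1) * dim, rows)
            for bx in range(geom.grid_dims[0]):
                if by == 0 and bx == 0:
                    continue
                x0, x1 = bx * dim, min((bx + 1) * dim, cols)
                out[y0:y1, x0:x1] = fn(*tile_args(y0, y1, x0, x1))

        with ThreadPoolExecutor(max_workers=self.workers) as pool:
            list(pool.map(run_block_row, range(geom.grid_dims[1])))
        return out


class GpuBackend(Backend):
    """CuPy-based execution; available only when CuPy and a device exist."""

    name = "gpu"

    def __init__(self) -> None:
        import cupy  # noqa: F401 — feature detection

        self._cp = cupy

    def elementwise(self, op_name: str, *operands: Any) -> np.ndarray:
        cp = self._cp
        fn = self._op(op_name)
        moved = [
            cp.asarray(op) if isinstance(op, np.ndarray) else op for op in operands
        ]
        return cp.asnumpy(fn(*moved))


def available_backends() -> list[str]:
    names = ["serial", "threads"]
    try:
        import cupy  # noqa: F401

        names.append("gpu")
    except Exception:
        pass
    return names


def get_backend(name: str | Backend = "serial") -> Backend:
    """Resolve a backend by name.  ``gpu`` raises a clear error when CuPy
    is not installed; install and tests never require it."""
    if isinstance(name, Backend):
        return name
    if name == "serial":
        return SerialBackend()
    if name == "threads":
        return ThreadsBackend()
    if name == "gpu":
        try:
            return GpuBackend()
        except Exception as exc:
            raise NotRegisteredError(
                f"GPU backend unavailable (CuPy import failed: {exc})"
            ) from exc
    raise NotRegisteredError(
        f"unknown backend {name!r}; choose from {available_backends()}"
    )
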