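"""Pre-reconstruction cleanup: histogram matching and median filtering.

The nine raw frames of an acquisition are recorded sequentially; source
drift and photobleaching leave them with slightly different intensity
statistics, which the band-separation step would misinterpret as
modulation.  Matching every frame's histogram to a common reference frame
equalises the statistics, and a small median filter suppresses impulsive
detector noise.  The fixed order is: match first, then filter.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.exposure import match_histograms

from .errors import DegenerateInputError, InvalidArgumentError
from .forward_sim import RawStack


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Square median filter with reflected edges.

    ``window`` must be odd; ``window = 1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidArgumentError(f"median window must be odd and >= 1, got {window}")
    return ndimage.median_filter(np.asarray(image, dtype=float), size=window, mode="reflect")


def histogram_match(source: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Monotone intensity remapping of ``source`` onto ``reference``'s histogram.

    The mapping is T = CDF_ref^-1 o CDF_src applied pixelwise (quantile
    mapping); it preserves pixel rank order and never produces values
    outside the reference range.
    """
    source = np.asarray(source, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0 or np.ptp(reference) == 0:
        raise DegenerateInputError(
            "histogram matching needs a non-constant, non-empty reference"
        )
    return match_histograms(source, reference)


def preprocess_stack(
    stack: RawStack, reference_index: int = 0, window: int = 3
) -> RawStack:
    """Histogram-match all frames to one reference frame, then median-filter.

    ``reference_index`` selects which of the 9 frames anchors the match
    (frame 0 by default).
    """
    if not 0 <= reference_index < 9:
        raise InvalidArgumentError(
            f"reference_index must be 0..8, got {reference_index}"
        )
    reference = stack.frames[reference_index]
    frames = np.stack(
        [
            median_filter(histogram_match(frame, reference), window)
            for frame in stack.frames
        ]
    )
    meta = dict(stack.meta)
    meta["preprocess"] = {"reference_index": reference_index, "median_window": window}
    return RawStack(frames=np.clip(frames, 0.0, None), meta=meta)
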