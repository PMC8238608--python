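"""Noise removal before segmentation: two-level adaptive median filtering.

The adaptive median filter classifies each pixel as impulse noise or signal
using a per-pixel window that grows until the window median is itself not an
extreme value (level A), then replaces the pixel only if the pixel is a
window extreme (level B).  This removes salt-and-pepper impulses, smooths
other noise, and leaves non-extreme detail untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class FilterConfig:
    """Window-size bounds of the adaptive median filter (both odd)."""

    initial_window: int = 3
    max_window: int = 7

    def __post_init__(self):
        if self.initial_window < 3 or self.initial_window % 2 == 0:
            raise ValueError("initial_window must be an odd integer >= 3")
        if self.max_window < self.initial_window or self.max_window % 2 == 0:
            raise ValueError("max_window must be odd and >= initial_window")


def to_uint8(image: np.ndarray) -> np.ndarray:
    """Quantize an arbitrary real-valued image to uint8.

    Float images with values in the unit interval are scaled by 255 (the
    usual float-image convention); values already in [0, 255] are clipped
    and rounded (so uint8 input is returned unchanged); any other range is
    linearly rescaled from [min, max] onto [0, 255].  A constant
    out-of-range image maps to 0.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValueError("empty image")
    mn, mx = float(arr.min()), float(arr.max())
    is_float = np.asarray(image).dtype.kind == "f"
    if is_float and 0.0 <= mn and mx <= 1.0:
        arr = arr * 255.0
    elif mn < 0.0 or mx > 255.0:
        if mx == mn:
            return np.zeros(arr.shape, dtype=np.uint8)
        arr = (arr - mn) / (mx - mn) * 255.0
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def adaptive_median_filter(image: np.ndarray,
                           config: FilterConfig | None = None) -> np.ndarray:
    """Two-level adaptive median filter with a growing window.

    For each pixel, starting at ``initial_window``: level A checks whether
    the window median lies strictly between the window min and max; if not,
    the window grows by 2 (outputting the median once ``max_window`` is
    reached).  Level B outputs the pixel unchanged when it lies strictly
    between the window min and max, else the window median.  Borders are
    reflect-padded.
    """
    config = config or FilterConfig()
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise TypeError("adaptive_median_filter expects a uint8 image")

    out = np.zeros_like(image)
    undecided = np.ones(image.shape, dtype=bool)
    for size in range(config.initial_window, config.max_window + 1, 2):
        med = ndimage.median_filter(image, size=size, mode="reflect")
        mn = ndimage.minimum_filter(image, size=size, mode="reflect")
        mx = ndimage.maximum_filter(image, size=size, mode="reflect")
        level_a = (mn < med) & (med < mx)
        decide = undecided & level_a
        pixel_ok = (mn < image) & (image < mx)
        out[decide] = np.where(pixel_ok[decide], image[decide], med[decide])
        undecided &= ~level_a
        if size == config.max_window:
            out[undecided] = med[undecided]  # window exhausted: emit median
    return out


__all__ = ["FilterConfig", "to_uint8", "adaptive_median_filter"]
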