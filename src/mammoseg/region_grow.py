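"""Seeded region growing with streaming region statistics.

The region mean and sample standard deviation (N-1 denominator) are updated
recursively as pixels are accepted:

    mu_N    = ((N-1) mu_{N-1} + I_N) / N
    sigma_N = sqrt( ((N-2) sigma_{N-1}^2 + (N/(N-1)) (I_N - mu_N)^2) / (N-1) )

and exactly reproduce the batch statistics of the accepted pixels.  Two
similarity criteria are supported, both with strict inequalities:

* ``std_band``:   mu - X*sigma < I < mu + X*sigma  (X = 3 by default, the
  band that contains ~99.7% of Gaussian samples);
* ``threshold``:  mu - X < I < mu + X              (X in gray levels).

The initial standard deviation is zero, which makes the std band empty; a
bootstrap phase applies the threshold criterion until ``bootstrap_min``
pixels have been accepted, and ``sigma_floor`` keeps the band non-degenerate
afterwards.  The frontier is a FIFO queue (breadth-first) with neighbors
enqueued in N, S, W, E, NW, NE, SW, SE order; a rejected pixel may be tested
again when the region reaches it from another accepted neighbor (the band
may have widened by then).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

# neighbor offsets in fixed enqueue order: N, S, W, E, NW, NE, SW, SE
_OFFSETS_8 = ((-1, 0), (1, 0), (0, -1), (0, 1),
              (-1, -1), (-1, 1), (1, -1), (1, 1))
_OFFSETS_4 = _OFFSETS_8[:4]


@dataclass
class RegionState:
    """Running pixel count, mean, and sample STD of a growing region."""

    count: int
    mean: float
    std: float = 0.0


@dataclass(frozen=True)
class GrowConfig:
    criterion: str = "std_band"  # or "threshold"
    X: float = 3.0
    connectivity: int = 8
    bootstrap_min: int = 9
    sigma_floor: float = 1.0

    def __post_init__(self):
        if self.criterion not in ("std_band", "threshold"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.X <= 0:
            raise ValueError("X must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.bootstrap_min < 2:
            raise ValueError("bootstrap_min must be >= 2")


def update_region_stats(state: RegionState, new_intensity: float) -> RegionState:
    """Fold one accepted intensity into the running mean/STD recursion."""
    n = state.count + 1
    i_n = float(new_intensity)
    mean = ((n - 1) * state.mean + i_n) / n
    if n >= 2:
        var = ((n - 2) * state.std**2 + (n / (n - 1)) * (i_n - mean) ** 2) / (n - 1)
        std = float(np.sqrt(max(var, 0.0)))
    else:
        std = 0.0
    return RegionState(count=n, mean=mean, std=std)


def accepts(state: RegionState, candidate_intensity: float,
            config: GrowConfig) -> bool:
    """Similarity test for one candidate pixel (strict band membership)."""
    i = float(candidate_intensity)
    if config.criterion == "threshold" or state.count < config.bootstrap_min:
        half = config.X
    else:
        half = config.X * max(state.std, config.sigma_floor)
    return (state.mean - half) < i < (state.mean + half)


def accepts_array(state: RegionState, candidate_intensities,
                  config: GrowConfig) -> np.ndarray:
    """Vectorized :func:`accepts` over an array of candidate intensities."""
    vals = np.asarray(candidate_intensities, dtype=float)
    if config.criterion == "threshold" or state.count < config.bootstrap_min:
        half = config.X
    else:
        half = config.X * max(state.std, config.sigma_floor)
    return (state.mean - half < vals) & (vals < state.mean + half)


def grow_region(image: np.ndarray, seed, config: GrowConfig | None = None,
                blocked: np.ndarray | None = None, offsets=None):
    """Grow one region from a seed; returns (mask, final RegionState).

    ``blocked`` marks pixels that may never join (used by :func:`grow_all`
    to keep regions disjoint); ``offsets`` overrides the neighbor enqueue
    order (defaults to N,S,W,E,NW,NE,SW,SE).  The returned {0,1} mask always
    contains the seed.
    """
    config = config or GrowConfig()
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    sr, sc = (seed.row, seed.col) if hasattr(seed, "row") else tuple(seed)
    if not (0 <= sr < h and 0 <= sc < w):
        raise ValueError(f"seed ({sr}, {sc}) out of bounds for {h}x{w} image")
    if offsets is None:
        offsets = _OFFSETS_8 if config.connectivity == 8 else _OFFSETS_4

    mask = np.zeros((h, w), dtype=np.uint8)
    mask[sr, sc] = 1
    state = RegionState(count=1, mean=float(img[sr, sc]), std=0.0)
    frontier = deque([(sr, sc)])
    while frontier:
        r, c = frontier.popleft()
        for dr, dc in offsets:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < w):
                continue
            if mask[nr, nc] or (blocked is not None and blocked[nr, nc]):
                continue
            val = img[nr, nc]
            if accepts(state, val, config):
                mask[nr, nc] = 1
                state = update_region_stats(state, val)
                frontier.append((nr, nc))
    return mask, state


def grow_all(image: np.ndarray, seeds=None, config: GrowConfig | None = None):
    """Partition the whole image into grown regions.

    Regions grow sequentially from the seed list (seeds falling in an
    already-grown region are skipped); once seeds are exhausted, the next
    seed is the first unassigned pixel in raster order, until every pixel
    carries exactly one label.  Returns ``(labels, k)`` with label 0 the
    first region.
    """
    config = config or GrowConfig()
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    h, w = img.shape
    labels = np.full((h, w), -1, dtype=np.int32)
    assigned = np.zeros((h, w), dtype=np.uint8)
    next_label = 0
    for seed in seeds or []:
        sr, sc = (seed.row, seed.col) if hasattr(seed, "row") else tuple(seed)
        if assigned[sr, sc]:
            continue
        mask, _ = grow_region(img, (sr, sc), config, blocked=assigned)
        labels[mask == 1] = next_label
        assigned |= mask
        next_label += 1
    while not assigned.all():
        flat = int(np.argmax(assigned == 0))  # first unassigned, raster order
        sr, sc = divmod(flat, w)
        mask, _ = grow_region(img, (sr, sc), config, blocked=assigned)
        labels[mask == 1] = next_label
        assigned |= mask
        next_label += 1
    return labels, next_label


__all__ = [
    "RegionState", "GrowConfig",
    "update_region_stats", "accepts", "accepts_array",
    "grow_region", "grow_all",
]
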