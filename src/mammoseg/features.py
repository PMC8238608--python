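"""Masked gray-level co-occurrence matrices and Haralick-style features.

The ROI (a segmented mass, or a reference tissue region for normal images)
is quantized to a small number of gray levels over its own intensity range,
then co-occurrence counts are accumulated over pixel pairs at a fixed offset
with *both* pixels inside the mask, so background texture never leaks into
the features.  Five classical scalar summaries are computed per matrix —
contrast, correlation, energy, homogeneity, entropy — and averaged over the
four unit offsets (0,1), (1,0), (1,1), (1,-1) with symmetric accumulation,
giving a rotation-robust five-number texture signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The four unit offsets (drow, dcol) averaged by extract_features.
UNIT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

FEATURE_NAMES = ("contrast", "correlation", "energy", "homogeneity", "entropy")


@dataclass(frozen=True)
class FeatureVector:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in FEATURE_NAMES}


def quantize(image: np.ndarray, mask: np.ndarray, levels: int = 16) -> np.ndarray:
    """Linearly bin masked intensities into [0, levels-1].

    Masked values are rescaled from [min, max] onto [0, 255] and binned as
    floor(v * levels / 256); a constant ROI maps to level 0.  Pixels outside
    the mask are set to 0 (they never enter a masked GLCM).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    img = np.asarray(image, dtype=float)
    vals = img[mask]
    mn, mx = vals.min(), vals.max()
    out = np.zeros(img.shape, dtype=np.int32)
    if mx > mn:
        scaled = (img - mn) / (mx - mn) * 255.0
        out[mask] = np.minimum(
            (scaled[mask] * levels / 256.0).astype(np.int32), levels - 1
        )
    return out


def glcm(quantized: np.ndarray, mask: np.ndarray, offset,
         levels: int | None = None, symmetric: bool = True) -> np.ndarray:
    """Normalized co-occurrence matrix of masked pixel pairs at one offset.

    P(i, j) is proportional to the number of pixel pairs (p, p+offset) with
    both endpoints inside the mask and quantized levels (i, j); symmetric
    accumulation adds the transpose before normalizing, so sum(P) = 1.
    """
    q = np.asarray(quantized)
    m = np.asarray(mask).astype(bool)
    if levels is None:
        levels = int(q[m].max()) + 1 if m.any() else 1
    dr, dc = offset
    h, w = q.shape
    r0a, r1a = max(0, -dr), min(h, h - dr)
    c0a, c1a = max(0, -dc), min(w, w - dc)
    src = (slice(r0a, r1a), slice(c0a, c1a))
    dst = (slice(r0a + dr, r1a + dr), slice(c0a + dc, c1a + dc))
    valid = m[src] & m[dst]
    i = q[src][valid]
    j = q[dst][valid]
    if i.size == 0:
        raise ValueError("no valid pixel pairs inside the mask at this offset")
    counts = np.bincount(i * levels + j, minlength=levels * levels).astype(float)
    P = counts.reshape(levels, levels)
    if symmetric:
        P = P + P.T
    return P / P.sum()


def haralick(P: np.ndarray) -> FeatureVector:
    """Five classical scalar summaries of a normalized GLCM.

    contrast    = sum (i-j)^2 P(i,j)
    correlation = sum (i-mu_r)(j-mu_c) P / (sigma_r sigma_c)   (0 if degenerate)
    energy      = sum P^2
    homogeneity = sum P / (1 + (i-j)^2)
    entropy     = -sum P log2 P   (0 log 0 := 0)
    """
    P = np.asarray(P, dtype=float)
    if abs(P.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalized (sum to 1)")
    L = P.shape[0]
    i, j = np.mgrid[0:L, 0:L]
    contrast = float(((i - j) ** 2 * P).sum())
    pr, pc = P.sum(axis=1), P.sum(axis=0)
    mu_r, mu_c = float((np.arange(L) * pr).sum()), float((np.arange(L) * pc).sum())
    var_r = float(((np.arange(L) - mu_r) ** 2 * pr).sum())
    var_c = float(((np.arange(L) - mu_c) ** 2 * pc).sum())
    if var_r > 0 and var_c > 0:
        correlation = float(
            (((i - mu_r) * (j - mu_c) * P).sum()) / np.sqrt(var_r * var_c)
        )
    else:
        correlation = 0.0
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0)), 0.0)
    entropy = float(-(P * logp).sum())
    return FeatureVector(contrast, correlation, energy, homogeneity, entropy)


def extract_features(image: np.ndarray, mask: np.ndarray,
                     levels: int = 16) -> FeatureVector:
    """Quantize the ROI and average the five features over the four unit
    offsets (symmetric GLCMs)."""
    q = quantize(image, mask, levels=levels)
    vecs = []
    for off in UNIT_OFFSETS:
        P = glcm(q, mask, off, levels=levels, symmetric=True)
        vecs.append(haralick(P).as_array())
    mean = np.mean(vecs, axis=0)
    return FeatureVector(*[float(v) for v in mean])


__all__ = [
    "UNIT_OFFSETS", "FEATURE_NAMES", "FeatureVector",
    "quantize", "glcm", "haralick", "extract_features",
]
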