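"""Synthetic mammogram-like phantoms with known ground truth.

A phantom is a bright breast region (half-ellipse anchored on the left image
edge, as in a medio-lateral view) on a dark background, optionally with a
brighter pectoral-muscle wedge in the top-left corner, and zero or one tumor:

* ``benign`` — a disk with a smooth radial intensity falloff and low,
  spatially smooth internal speckle (well-circumscribed, homogeneous mass);
* ``malignant`` — a spiculated star polygon whose heterogeneous interior is
  modeled as punctate high-amplitude foci (microcalcification-like bright
  and dark specks) scaled to the requested texture standard deviation;
* ``normal`` — no tumor, all-zero truth mask.

Benign and malignant masses differ both in boundary regularity and interior
texture so that GLCM features carry class signal.  Everything is driven by a
single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .preprocess import to_uint8

#: Fixed class order used by make_dataset and everything downstream.
CLASS_ORDER = ("normal", "benign", "malignant")

# Fixed phantom geometry/intensity constants (fractions of H/W where spatial).
BACKGROUND_LEVEL = 15.0
BREAST_LEVEL = 110.0
WEDGE_LEVEL = 145.0
BREAST_SEMI_AXES = (0.47, 0.59)  # (row, col) semi-axes of the half-ellipse
WEDGE_EXTENT = (0.23, 0.31)      # (row, col) legs of the corner triangle
TISSUE_TEXTURE_SIGMA = 3.0       # gray levels of smooth fibroglandular texture
TISSUE_TEXTURE_SCALE = 8.0       # blur radius (px) of that texture
BENIGN_SPECKLE_SCALE = 2.0       # blur radius of benign interior speckle
PUNCTATE_DENSITY = 0.25          # fraction of malignant interior pixels with foci
FALLOFF_EDGE_FRACTION = 0.6      # intensity at the mass edge relative to center


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is geometrically invalid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic image; defaults are the study conditions."""

    height: int = 256
    width: int = 256
    tumor_class: str = "benign"
    tumor_center: tuple[int, int] | None = None  # None -> auto placement
    tumor_radius: float = 20.0
    tumor_contrast: float = 60.0
    spiculation: int = 8
    texture_sigma: float | None = None  # None -> class default (benign 2, malignant 12)
    background_sigma: float = 5.0
    impulse_density: float = 0.0
    pectoral_wedge: bool = False
    rng_seed: int = 0

    def resolved_texture_sigma(self) -> float:
        if self.texture_sigma is not None:
            return float(self.texture_sigma)
        return 12.0 if self.tumor_class == "malignant" else 2.0

    def resolved_center(self) -> tuple[int, int]:
        if self.tumor_center is not None:
            return tuple(self.tumor_center)
        return (int(0.43 * self.height), int(0.23 * self.width))


def _breast_mask(h: int, w: int) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    a = BREAST_SEMI_AXES[0] * h
    b = BREAST_SEMI_AXES[1] * w
    return ((rr - 0.5 * h) / a) ** 2 + (cc / b) ** 2 <= 1.0


def _wedge_mask(h: int, w: int) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    return rr / (WEDGE_EXTENT[0] * h) + cc / (WEDGE_EXTENT[1] * w) < 1.0


def _correlated_noise(shape, scale: float, target_sigma: float, rng) -> np.ndarray:
    """Gaussian-blurred white noise rescaled to a target standard deviation."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), scale, mode="reflect")
    sd = field.std()
    if sd == 0:
        return np.zeros(shape)
    return field * (target_sigma / sd)


def _tumor_support(spec: PhantomSpec, phase: float):
    """Tumor mask plus the per-pixel normalized radial coordinate in [0,1]."""
    h, w = spec.height, spec.width
    cr, cc = spec.resolved_center()
    rr, col = np.mgrid[0:h, 0:w]
    dr, dc = rr - cr, col - cc
    dist = np.hypot(dr, dc)
    if spec.tumor_class == "malignant":
        theta = np.arctan2(dr, dc)
        # star polygon: spikes via a sharpened cosine of the angular coordinate
        r_theta = spec.tumor_radius * (
            0.55 + 0.45 * np.cos(spec.spiculation * theta + phase) ** 4
        )
    else:
        r_theta = np.full((h, w), float(spec.tumor_radius))
    mask = dist <= r_theta
    rel = np.where(mask, dist / np.maximum(r_theta, 1e-12), 1.0)
    return mask, rel


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns ``(image, mask, class_label)`` where ``image`` is uint8,
    ``mask`` is the exact {0,1} tumor support (all zero for ``normal``)
    and ``class_label`` is ``spec.tumor_class``.
    """
    if spec.tumor_class not in CLASS_ORDER:
        raise PhantomSpecError(f"unknown tumor_class {spec.tumor_class!r}")
    if not (0.0 <= spec.impulse_density < 1.0):
        raise PhantomSpecError("impulse_density must be in [0, 1)")
    if spec.tumor_class != "normal" and spec.tumor_contrast <= 0:
        raise PhantomSpecError("tumor_contrast must be positive")

    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.rng_seed)
    breast = _breast_mask(h, w)

    img = np.full((h, w), BACKGROUND_LEVEL)
    img[breast] = BREAST_LEVEL
    tissue = _correlated_noise((h, w), TISSUE_TEXTURE_SCALE, TISSUE_TEXTURE_SIGMA, rng)
    img[breast] += tissue[breast]
    if spec.pectoral_wedge:
        img[_wedge_mask(h, w)] = WEDGE_LEVEL

    mask = np.zeros((h, w), dtype=np.uint8)
    if spec.tumor_class != "normal":
        phase = rng.uniform(0, 2 * np.pi)
        support, rel = _tumor_support(spec, phase)
        if not support.any():
            raise PhantomSpecError("tumor support is empty")
        if not breast[support].all():
            raise PhantomSpecError("tumor does not fit inside the breast region")
        falloff = 1.0 - (1.0 - FALLOFF_EDGE_FRACTION) * rel**2
        img[support] = BREAST_LEVEL + spec.tumor_contrast * falloff[support]
        tex = spec.resolved_texture_sigma()
        if spec.tumor_class == "malignant":
            # punctate bright foci (microcalcification-like) at density rho;
            # amplitude set so the interior speckle STD equals texture_sigma:
            # std(Bernoulli(rho) * A) = A sqrt(rho (1 - rho))
            rho = PUNCTATE_DENSITY
            amp = tex / np.sqrt(rho * (1.0 - rho))
            foci = amp * (rng.random(int(support.sum())) < rho)
            img[support] += foci
        else:
            speckle = _correlated_noise((h, w), BENIGN_SPECKLE_SCALE, tex, rng)
            img[support] += speckle[support]
        mask[support] = 1

    img = img + rng.normal(0.0, spec.background_sigma, size=(h, w))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if spec.impulse_density > 0:
        img, _ = add_impulse_noise(img, spec.impulse_density, rng)
    return img, mask, spec.tumor_class


def add_impulse_noise(image: np.ndarray, density: float, rng_seed):
    """Corrupt exactly ``round(density*H*W)`` pixels with salt (255) or pepper (0).

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    Returns the corrupted image and the {0,1} corruption mask.
    """
    if not (0.0 <= density < 1.0):
        raise ValueError("density must be in [0, 1)")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    image = np.asarray(image)
    h, w = image.shape
    n_bad = int(round(density * h * w))
    out = image.copy()
    corrupted = np.zeros((h, w), dtype=np.uint8)
    if n_bad == 0:
        return out, corrupted
    flat_idx = rng.choice(h * w, size=n_bad, replace=False)
    values = rng.choice(np.array([0, 255], dtype=image.dtype), size=n_bad)
    out.flat[flat_idx] = values
    corrupted.flat[flat_idx] = 1
    return out, corrupted


def make_dataset(n_per_class: int, spec_template: PhantomSpec | None = None,
                 rng_seed: int = 0):
    """Generate ``3*n_per_class`` phantoms, grouped normal, benign, malignant.

    Tumor centers and radii are jittered inside the breast; each item gets its
    own deterministic child seed so the dataset is reproducible item by item.
    Returns a list of ``(image, mask, class_label)`` triples.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    template = spec_template or PhantomSpec()
    master = np.random.default_rng(rng_seed)
    items = []
    for cls in CLASS_ORDER:
        for _ in range(n_per_class):
            child_seed = int(master.integers(0, 2**31 - 1))
            jitter = np.random.default_rng(child_seed)
            row = int(jitter.uniform(0.33, 0.63) * template.height)
            col = int(jitter.uniform(0.16, 0.36) * template.width)
            radius = float(jitter.uniform(0.75, 1.25) * template.tumor_radius)
            spec = replace(
                template,
                tumor_class=cls,
                tumor_center=(row, col),
                tumor_radius=radius,
                rng_seed=child_seed,
            )
            items.append(generate_phantom(spec))
    return items


__all__ = [
    "CLASS_ORDER",
    "PhantomSpec",
    "PhantomSpecError",
    "generate_phantom",
    "add_impulse_noise",
    "make_dataset",
    "to_uint8",
]
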