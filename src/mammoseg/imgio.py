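"""Raster and tabular I/O for the segmentation pipeline.

Images are plain 2-D numpy arrays (``GrayImage``): row index increases
downward, column index rightward, indices are 0-based, and uint8 content is
in [0, 255].  Binary masks are {0, 1} uint8 arrays of the same shape as the
image they annotate; label images are small non-negative integer arrays with
``k`` labels in ``[0, k-1]``.

Supported raster formats are PGM (P2/P5), PNG and TIFF via Pillow.  Feature
tables are CSV with a fixed schema; reports and sidecar metadata are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

#: ITU-R 601 luminance weights used for color -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Required columns of a feature table, in canonical order.
FEATURE_COLUMNS = [
    "id",
    "class_label",
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
    "entropy",
]

_RASTER_SUFFIXES = {".pgm", ".png", ".tif", ".tiff"}


class ImageFormatError(ValueError):
    """Raised when a file cannot be read as a supported raster format."""


class SchemaError(ValueError):
    """Raised when a tabular file is missing required columns."""


def to_gray(rgb: np.ndarray) -> np.ndarray:
    """Collapse an H×W×C array to luminance (uint8, rounded)."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim == 2:
        return np.rint(rgb).astype(np.uint8)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    w = LUMA_WEIGHTS
    return np.rint(w[0] * r + w[1] * g + w[2] * b).astype(np.uint8)


def read_image(path) -> np.ndarray:
    """Read a PGM/PNG/TIFF file as a 2-D uint8 GrayImage.

    Multi-channel inputs are converted by luminance weights
    0.299 R + 0.587 G + 0.114 B and rounded; an alpha channel is ignored.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise ImageFormatError(f"cannot read image file {path!s}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        return to_gray(arr)
    if arr.ndim != 2:
        raise ImageFormatError(f"unsupported image dimensionality in {path!s}")
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(float)), 0, 255).astype(np.uint8)
    return arr


def write_image(image: np.ndarray, path) -> None:
    """Write a GrayImage, BinaryMask or LabelImage to a raster file.

    Masks (pure {0,1} content) are scaled to 0/255.  Use
    :func:`write_labels` for label images so the label count is recorded.
    """
    path = Path(path)
    if path.suffix.lower() not in _RASTER_SUFFIXES:
        raise ImageFormatError(f"unsupported raster extension: {path.suffix!r}")
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ImageFormatError("only 2-D images can be written")
    if arr.dtype == bool or (arr.size and set(np.unique(arr)) <= {0, 1}):
        arr = (arr.astype(np.uint8)) * 255
    arr = arr.astype(np.uint8)
    try:
        Image.fromarray(arr, mode="L").save(path)
    except OSError as exc:
        raise OSError(f"cannot write image file {path!s}: {exc}") from exc


def write_mask(mask: np.ndarray, path) -> None:
    """Write a {0,1} mask as a 0/255 8-bit raster."""
    write_image(np.asarray(mask, dtype=np.uint8) * 255, path)


def read_mask(path) -> np.ndarray:
    """Read a 0/255 (or any nonzero-foreground) raster as a {0,1} mask."""
    return (read_image(path) > 0).astype(np.uint8)


def write_labels(labels: np.ndarray, k: int, path) -> None:
    """Write a LabelImage as raw labels plus a ``<path>.json`` sidecar with k."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels out of range for k={k}")
    # raw labels, not mask-scaled: bypass write_image's {0,1} heuristic
    Image.fromarray(labels.astype(np.uint8), mode="L").save(path)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({"k": int(k)}))


def read_labels(path) -> tuple[np.ndarray, int]:
    """Read a LabelImage and its sidecar label count."""
    with Image.open(path) as im:
        labels = np.asarray(im).astype(np.int64)
    sidecar = Path(str(path) + ".json")
    k = int(json.loads(sidecar.read_text())["k"])
    if labels.max() >= k:
        raise ValueError(f"label {labels.max()} out of range for k={k}")
    return labels, k


def write_report(report: dict, path) -> None:
    """Write a metric-name -> number mapping as JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def write_features(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV with 12 significant digits."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing required columns: {missing}")
    table.to_csv(path, index=False, float_format="%.12g")


def read_features(path) -> pd.DataFrame:
    """Read a feature CSV, validating the required schema."""
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature file {path!s} missing columns: {missing}")
    return table
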