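"""Image, mask and reference-table I/O.

Conventions used throughout the package:

* images are ``numpy.uint8`` arrays, shape ``(rows, cols)`` for a single
  channel or ``(rows, cols, 3)`` for RGB;
* coordinates are 0-based, row-major, origin at the top-left corner, and
  positions are always reported as ``(row, col)``;
* binary masks take values in ``{0, 255}`` with 255 = fruit (foreground).

Masks are persisted as single-channel PNG.  On read, any nonzero pixel is
normalized to 255 so that hand-painted ground truths with stray
antialiased values are ingested tolerantly.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

__all__ = [
    "SchemaError",
    "TableValidationError",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_reference_table",
    "ensure_rgb",
    "ensure_mask",
]

#: required columns of a reference-measurement CSV
REFERENCE_COLUMNS = (
    "image_id",
    "fruit_id",
    "major_axis_mm",
    "minor_axis_mm",
    "mass_g",
    "approx_row",
    "approx_col",
)


class SchemaError(ValueError):
    """A table is missing required columns."""


class TableValidationError(ValueError):
    """Table rows violate the reference-measurement invariants."""


def ensure_rgb(image: np.ndarray) -> np.ndarray:
    """Validate that *image* is an 8-bit RGB raster and return it."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise TypeError(
            f"expected an RGB image of shape (rows, cols, 3), got shape {image.shape}"
        )
    if image.dtype != np.uint8:
        raise TypeError(f"expected uint8 pixel data, got {image.dtype}")
    return image


def ensure_mask(mask: np.ndarray) -> np.ndarray:
    """Validate that *mask* is a single-channel {0, 255} raster and return it."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise TypeError(f"expected a 2-D mask, got shape {mask.shape}")
    if mask.dtype != np.uint8:
        raise TypeError(f"expected uint8 mask data, got {mask.dtype}")
    bad = np.setdiff1d(np.unique(mask), [0, 255])
    if bad.size:
        raise ValueError(f"mask contains values outside {{0, 255}}: {bad.tolist()}")
    return mask


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a JPG/PNG photograph as a uint8 array.

    Returns shape ``(rows, cols, 3)`` for color input or ``(rows, cols)``
    for grayscale input.
    """
    try:
        with Image.open(path) as im:
            if im.mode in ("1", "L", "I;16", "I"):
                im = im.convert("L")
            else:
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except FileNotFoundError:
        raise IOError(f"image file not found: {path}") from None
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot decode image file {path}: {exc}") from exc
    return arr


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB or grayscale uint8 image as lossless PNG."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise TypeError(f"expected uint8 image, got {image.dtype}")
    try:
        Image.fromarray(image).save(path, format="PNG")
    except OSError as exc:
        raise IOError(f"cannot write image to {path}: {exc}") from exc


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask PNG; any nonzero pixel is normalized to 255."""
    arr = read_image(path)
    if arr.ndim == 3:  # tolerate RGB-saved ground truths
        arr = arr.max(axis=2)
    return np.where(arr > 0, 255, 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a {0, 255} mask as single-channel lossless PNG."""
    write_image(ensure_mask(mask), path)


def read_reference_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a CSV of per-fruit reference measurements.

    The table must provide :data:`REFERENCE_COLUMNS`: caliper axis lengths in
    mm, balance mass in g, and the approximate (row, col) position of each
    fruit in its photograph.  Rows violating the measurement invariants are
    rejected with their (0-based, header-excluded) row numbers.
    """
    if not os.path.exists(path):
        raise IOError(f"reference table not found: {path}")
    table = pd.read_csv(path)
    missing = [c for c in REFERENCE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"reference table {path} is missing columns: {missing}")

    problems: list[str] = []
    numeric = ["major_axis_mm", "minor_axis_mm", "mass_g", "approx_row", "approx_col"]
    for col in numeric:
        bad = table.index[pd.to_numeric(table[col], errors="coerce").isna()]
        if len(bad):
            problems.append(f"non-numeric {col} in rows {bad.tolist()}")
    if not problems:
        table[numeric] = table[numeric].astype(float)
        bad = table.index[table["mass_g"] <= 0]
        if len(bad):
            problems.append(f"non-positive mass_g in rows {bad.tolist()}")
        bad = table.index[table["minor_axis_mm"] <= 0]
        if len(bad):
            problems.append(f"non-positive minor_axis_mm in rows {bad.tolist()}")
        bad = table.index[table["major_axis_mm"] < table["minor_axis_mm"]]
        if len(bad):
            problems.append(f"major_axis_mm < minor_axis_mm in rows {bad.tolist()}")
        dup = table.index[table.duplicated(subset=["image_id", "fruit_id"], keep=False)]
        if len(dup):
            problems.append(f"duplicate (image_id, fruit_id) in rows {dup.tolist()}")
    if problems:
        raise TableValidationError(
            f"invalid reference table {path}: " + "; ".join(problems)
        )
    return table
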