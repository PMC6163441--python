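"""Fruit segmentation on bright-mat photographs.

The algorithm maximizes fruit/background contrast by fusing the HSV
saturation channel with the inverted value channel, flattens the mat's
brightness folds by subtracting a morphological (opening-based) background
estimate, binarizes with Otsu's clustering threshold, and finally cleans
the mask with a small opening and fills specular-highlight holes by
morphological reconstruction.

Why S + (255 - V)?  On a bright, weakly saturated mat both terms are near
zero for background pixels — including shadow pixels, which are darker but
remain weakly saturated — while fruit pixels are both darker (large
255 - V) and more saturated, so the fused image is near-black background
with bright fruit blobs.

All structuring elements are Euclidean-distance disks
``{(dr, dc): dr^2 + dc^2 <= r^2}`` and all filters and morphological
operators use edge-inclusive reflect padding at the borders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.morphology import reconstruction

from .raster_io import ensure_mask, ensure_rgb

__all__ = [
    "SegmentationConfig",
    "DegenerateHistogramError",
    "disk_footprint",
    "preprocess",
    "split_hsv",
    "invert_value",
    "fuse_channels",
    "estimate_background",
    "subtract_background",
    "otsu_threshold",
    "binarize",
    "clean_mask",
    "fill_holes",
    "segment",
]

logger = logging.getLogger(__name__)


class DegenerateHistogramError(ValueError):
    """Otsu thresholding is undefined: the histogram occupies a single bin."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation pipeline.

    Defaults reproduce the reference operating point: 40% bicubic
    down-scaling, a 5x5 Gaussian with sigma 0.8 px, a 50-px-radius disk for
    background estimation (large enough to contain any fruit at working
    resolution) and a 3-px-radius disk for small-blob removal.

    ``wide_range=True`` switches the channel fusion and background
    subtraction from saturating 8-bit arithmetic to full-range integer
    arithmetic with a linear rescale to [0, 255] before thresholding.
    """

    scale_factor: float = 0.40
    gaussian_sigma: float = 0.8
    gaussian_kernel: int = 5
    bg_disk_radius: int = 50
    clean_disk_radius: int = 3
    wide_range: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.scale_factor <= 1.0:
            raise ValueError(f"scale_factor must be in (0, 1], got {self.scale_factor}")
        if self.gaussian_sigma <= 0:
            raise ValueError(f"gaussian_sigma must be > 0, got {self.gaussian_sigma}")
        k = self.gaussian_kernel
        if k < 3 or k % 2 == 0:
            raise ValueError(f"gaussian_kernel must be odd and >= 3, got {k}")
        if self.bg_disk_radius < 1 or self.clean_disk_radius < 1:
            raise ValueError("structuring-element radii must be >= 1")

    def with_options(self, **kwargs) -> "SegmentationConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# structuring elements and fast flat morphology
# ---------------------------------------------------------------------------

def disk_footprint(radius: int) -> np.ndarray:
    """Boolean Euclidean disk {(dr, dc): dr^2 + dc^2 <= r^2}."""
    r = int(radius)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return (dr * dr + dc * dc) <= r * r


def _disk_halfwidths(radius: int) -> np.ndarray:
    """Horizontal half-extent of the disk at each row offset -r..r."""
    r = int(radius)
    dr = np.arange(-r, r + 1)
    return np.floor(np.sqrt(r * r - dr * dr.astype(float))).astype(int)


def _disk_rank_filter(image: np.ndarray, radius: int, maximum: bool) -> np.ndarray:
    """Flat erosion (min) or dilation (max) by a Euclidean disk.

    The disk is decomposed into its horizontal runs; each run is a 1-D
    running min/max, so the cost is O(radius) 1-D passes instead of
    O(radius^2) neighbours per pixel.  Borders use edge-inclusive
    reflection, i.e. the filter acts on np.pad(..., mode="symmetric").
    """
    r = int(radius)
    padded = np.pad(image, r, mode="symmetric")
    filt = ndimage.maximum_filter1d if maximum else ndimage.minimum_filter1d
    rows, cols = image.shape
    # one 1-D pass per distinct run half-width, shared across row offsets
    halfwidths = _disk_halfwidths(r)
    row_filtered = {w: filt(padded, 2 * w + 1, axis=1) for w in np.unique(halfwidths)}
    out = None
    for dr, w in zip(range(-r, r + 1), halfwidths):
        window = row_filtered[w][r + dr : r + dr + rows, r : r + cols]
        if out is None:
            out = window.copy()
        elif maximum:
            np.maximum(out, window, out=out)
        else:
            np.minimum(out, window, out=out)
    return out


def _grey_opening_disk(image: np.ndarray, radius: int) -> np.ndarray:
    eroded = _disk_rank_filter(image, radius, maximum=False)
    return _disk_rank_filter(eroded, radius, maximum=True)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _gaussian_kernel2d(sigma: float, size: int) -> np.ndarray:
    """Truncated rotationally symmetric Gaussian, renormalized to sum 1."""
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    dr, dc = np.meshgrid(ax, ax, indexing="ij")
    kernel = np.exp(-(dr * dr + dc * dc) / (2.0 * sigma * sigma))
    return kernel / kernel.sum()


def preprocess(image: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Down-scale by bicubic interpolation, then Gaussian-smooth each channel."""
    image = ensure_rgb(image)
    if config.scale_factor < 1.0:
        rows, cols = image.shape[:2]
        new_cols = max(1, round(cols * config.scale_factor))
        new_rows = max(1, round(rows * config.scale_factor))
        image = np.asarray(
            Image.fromarray(image).resize((new_cols, new_rows), Image.BICUBIC),
            dtype=np.uint8,
        )
    kernel = _gaussian_kernel2d(config.gaussian_sigma, config.gaussian_kernel)
    out = np.empty_like(image, dtype=np.float64)
    for ch in range(3):
        out[..., ch] = ndimage.correlate(
            image[..., ch].astype(np.float64), kernel, mode="reflect"
        )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def split_hsv(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hexcone saturation and value channels, each rescaled to [0, 255].

    V = max(R, G, B); S = 0 where V = 0, else 255 * (V - min(R, G, B)) / V,
    rounded to the nearest integer.
    """
    image = ensure_rgb(image)
    v = image.max(axis=2)
    mn = image.min(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(v == 0, 0.0, 255.0 * (v - mn) / np.where(v == 0, 1, v))
    return np.rint(s).astype(np.uint8), v.astype(np.uint8)


# ---------------------------------------------------------------------------
# channel fusion and background subtraction
# ---------------------------------------------------------------------------

def invert_value(v: np.ndarray) -> np.ndarray:
    """Per-pixel 255 - V: fruits become bright, the mat becomes dark."""
    v = np.asarray(v)
    if v.ndim != 2:
        raise TypeError(f"expected a single channel, got shape {v.shape}")
    return (255 - v.astype(np.int64)).astype(v.dtype if v.dtype == np.uint8 else np.uint8)


def fuse_channels(s: np.ndarray, v_inv: np.ndarray, saturate: bool = True) -> np.ndarray:
    """S + V_inv; saturating 8-bit addition (default) or full-range int32."""
    s = np.asarray(s)
    v_inv = np.asarray(v_inv)
    if s.shape != v_inv.shape:
        raise ValueError(f"shape mismatch: S {s.shape} vs V_inv {v_inv.shape}")
    total = s.astype(np.int32) + v_inv.astype(np.int32)
    if not saturate:
        return total
    return np.minimum(total, 255).astype(np.uint8)


def estimate_background(i_sv: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening with a disk large enough to contain any fruit.

    The opening removes every bright structure in which the disk does not
    fit — i.e. the fruit blobs — leaving the smooth residual background
    (mat folds, vignetting).  Anti-extensive: output <= input everywhere.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    return _grey_opening_disk(np.asarray(i_sv), int(radius))


def subtract_background(i_sv: np.ndarray, i_bg: np.ndarray) -> np.ndarray:
    """Per-pixel max(I_SV - I_bg, 0), yielding the high-contrast image."""
    i_sv = np.asarray(i_sv)
    i_bg = np.asarray(i_bg)
    if i_sv.shape != i_bg.shape:
        raise ValueError(f"shape mismatch: {i_sv.shape} vs {i_bg.shape}")
    diff = i_sv.astype(np.int64) - i_bg.astype(np.int64)
    np.maximum(diff, 0, out=diff)
    if i_sv.dtype == np.uint8 and i_bg.dtype == np.uint8:
        return diff.astype(np.uint8)
    return diff


def _rescale_to_uint8(image: np.ndarray) -> np.ndarray:
    """Linear rescale of an integer image to [0, 255] (wide-range mode)."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    return np.rint(255.0 * (image - lo) / (hi - lo)).astype(np.uint8)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's clustering threshold on the 256-bin histogram.

    Returns the t in [0, 254] maximizing the between-class variance of the
    two pixel populations split as {<= t} / {> t}; ties break toward the
    smallest t.  A single-bin (constant) histogram has no two classes to
    separate and raises :class:`DegenerateHistogramError`.
    """
    image = np.asarray(image)
    if image.min() < 0 or image.max() > 255:
        raise ValueError("image values must lie in [0, 255]")
    hist = np.bincount(image.astype(np.int64).ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "constant image: Otsu threshold is undefined for a single-bin histogram"
        )
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # pixels <= t
    m0 = np.cumsum(hist * levels)  # intensity mass <= t
    mu_total = m0[-1] / n
    w0_t = w0[:-1]
    w1_t = n - w0_t
    valid = (w0_t > 0) & (w1_t > 0)
    mu0 = np.where(valid, m0[:-1] / np.where(w0_t > 0, w0_t, 1), 0.0)
    mu1 = np.where(valid, (m0[-1] - m0[:-1]) / np.where(w1_t > 0, w1_t, 1), 0.0)
    sigma_b = np.where(valid, w0_t * w1_t * (mu0 - mu1) ** 2, -np.inf)
    del mu_total
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def binarize(image: np.ndarray, threshold: int) -> np.ndarray:
    """Strict thresholding: pixel > t -> 255, else 0."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    return np.where(np.asarray(image) > threshold, 255, 0).astype(np.uint8)


# ---------------------------------------------------------------------------
# mask postprocessing
# ---------------------------------------------------------------------------

def clean_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary opening with a disk: removes components too small to be fruit."""
    mask = ensure_mask(mask)
    return _grey_opening_disk(mask, int(radius))


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed background holes by morphological reconstruction.

    Reconstruction by erosion from a marker that keeps the mask value on
    the image border and is foreground everywhere else; iterated to
    idempotence.  Equivalently: every background region not 4-connected to
    the border becomes foreground.  Holes arise from specular highlights
    on the convex fruit surface; genuine background always reaches the
    border.  Extensive (never removes foreground) and idempotent.
    """
    mask = ensure_mask(mask)
    if mask.size == 0 or mask.shape[0] < 3 or mask.shape[1] < 3:
        return mask.copy()
    marker = np.full(mask.shape, 255, dtype=np.uint8)
    marker[0, :] = mask[0, :]
    marker[-1, :] = mask[-1, :]
    marker[:, 0] = mask[:, 0]
    marker[:, -1] = mask[:, -1]
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    filled = reconstruction(marker, mask, method="erosion", footprint=cross)
    return filled.astype(np.uint8)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def segment(image: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Run the full segmentation pipeline on an RGB photograph.

    preprocess -> split_hsv -> invert_value -> fuse_channels ->
    estimate_background -> subtract_background -> otsu_threshold ->
    binarize -> clean_mask -> fill_holes.  The returned mask has the
    down-scaled (working-resolution) shape.  A degenerate Otsu histogram
    (e.g. an empty mat) yields an all-background mask and a logged warning.
    """
    config = config or SegmentationConfig()
    pre = preprocess(image, config)
    s, v = split_hsv(pre)
    fused = fuse_channels(s, invert_value(v), saturate=not config.wide_range)
    background = estimate_background(fused, config.bg_disk_radius)
    high_contrast = subtract_background(fused, background)
    if config.wide_range:
        high_contrast = _rescale_to_uint8(high_contrast)
    try:
        threshold = otsu_threshold(high_contrast)
    except DegenerateHistogramError:
        logger.warning(
            "degenerate histogram after background subtraction; returning empty mask"
        )
        return np.zeros(high_contrast.shape, dtype=np.uint8)
    mask = binarize(high_contrast, threshold)
    mask = clean_mask(mask, config.clean_disk_radius)
    return fill_holes(mask)
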