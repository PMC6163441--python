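"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results from first principles
(explicit neighbourhood loops, exhaustive searches, BFS) so the fast
implementations are checked against a fully independent path.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from olivemeter import synthgen

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def brute_rank_filter(image: np.ndarray, radius: int, maximum: bool) -> np.ndarray:
    """Erosion/dilation by a Euclidean disk via explicit neighbourhood scan,
    with edge-inclusive reflect padding."""
    padded = np.pad(image, radius, mode="symmetric").astype(np.int64)
    rows, cols = image.shape
    out = np.empty((rows, cols), dtype=np.int64)
    offsets = disk_offsets(radius)
    reduce_ = max if maximum else min
    for r in range(rows):
        for c in range(cols):
            out[r, c] = reduce_(
                padded[r + radius + dr, c + radius + dc] for dr, dc in offsets
            )
    return out.astype(image.dtype)


def brute_opening(image: np.ndarray, radius: int) -> np.ndarray:
    return brute_rank_filter(brute_rank_filter(image, radius, False), radius, True)


def brute_otsu(image: np.ndarray) -> int:
    """Exhaustive search over all 255 candidate thresholds."""
    hist = np.bincount(np.asarray(image).ravel(), minlength=256)
    n = hist.sum()
    levels = np.arange(256)
    best_t, best_v = None, -np.inf
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def bfs_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected labeling by breadth-first flood fill, raster seed order."""
    fg = np.asarray(mask) > 0
    labels = np.zeros(fg.shape, dtype=np.int32)
    count = 0
    for r in range(fg.shape[0]):
        for c in range(fg.shape[1]):
            if fg[r, c] and labels[r, c] == 0:
                count += 1
                queue = deque([(r, c)])
                labels[r, c] = count
                while queue:
                    rr, cc = queue.popleft()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (
                                0 <= nr < fg.shape[0]
                                and 0 <= nc < fg.shape[1]
                                and fg[nr, nc]
                                and labels[nr, nc] == 0
                            ):
                                labels[nr, nc] = count
                                queue.append((nr, nc))
    return labels, count


def filled_ellipse(shape, center, a, b, theta) -> np.ndarray:
    """Digital filled ellipse mask (semi-axes a >= b in px)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dc * np.cos(theta) + dr * np.sin(theta)
    w = -dc * np.sin(theta) + dr * np.cos(theta)
    inside = (u / a) ** 2 + (w / b) ** 2 <= 1.0
    return np.where(inside, 255, 0).astype(np.uint8)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

SMALL_SCENE_PARAMS = synthgen.SceneParams(image_size=(896, 1408), n_fruits=4, seed=3)


@pytest.fixture(scope="session")
def small_scene():
    """A compact 4-fruit scene reused across segmentation/feature tests."""
    image, truth = synthgen.generate_scene(SMALL_SCENE_PARAMS)
    return image, truth


@pytest.fixture(scope="session")
def small_scene_mask(small_scene):
    from olivemeter import segmentation

    image, _ = small_scene
    return segmentation.segment(image)
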