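"""Connected-component analysis and per-fruit shape descriptors.

Each fruit appears in the binary mask as one 8-connected component.  Its
size is described by the pixel count (area) and by the axes of the ellipse
sharing the component's normalized second central moments: the covariance
matrix of the pixel coordinates, with 1/12 added to both diagonal entries
so that each pixel contributes the second moment of a unit square.  The
full axis lengths are 4*sqrt(eigenvalue) — the unique scaling for which a
filled continuous ellipse returns its true axis lengths.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from skimage.measure import label as _sklabel

from .raster_io import ensure_mask

__all__ = [
    "AmbiguousMatchError",
    "COMPONENT_COLUMNS",
    "label_components",
    "ellipse_axes",
    "measure_components",
    "match_to_reference",
]

COMPONENT_COLUMNS = (
    "label",
    "area_px",
    "centroid_row",
    "centroid_col",
    "major_axis_px",
    "minor_axis_px",
    "orientation_rad",
)


class AmbiguousMatchError(ValueError):
    """Two reference fruits are equally near the same component."""


def label_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected labeling of mask foreground.

    Background is 0; labels are 1..count, ordered by each component's first
    pixel in row-major scan order (deterministic across platforms).
    """
    mask = ensure_mask(mask)
    raw, count = _sklabel(mask > 0, connectivity=2, return_num=True)
    if count == 0:
        return raw.astype(np.int32), 0
    # relabel by first-occurrence scan order
    flat = raw.ravel()
    first = np.full(count + 1, flat.size, dtype=np.int64)
    nonzero = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first[flat[nonzero[::-1]]] = nonzero[::-1]
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(count + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, count + 1, dtype=np.int32)
    return remap[raw], count


def ellipse_axes(coords: np.ndarray) -> tuple[float, float, float]:
    """Axis lengths and orientation of the moment-equivalent ellipse.

    Parameters
    ----------
    coords : (n, 2) array of (row, col) pixel coordinates of one component.

    Returns
    -------
    (major_axis_px, minor_axis_px, orientation_rad) where orientation is
    the angle of the major axis relative to the column (horizontal) axis,
    measured toward increasing row index, in (-pi/2, pi/2].
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] == 0:
        raise ValueError("coords must be a non-empty (n, 2) array of (row, col)")
    centered = coords - coords.mean(axis=0)
    n = coords.shape[0]
    # population covariance + unit-pixel-extent correction
    crr = centered[:, 0] @ centered[:, 0] / n + 1.0 / 12.0
    ccc = centered[:, 1] @ centered[:, 1] / n + 1.0 / 12.0
    crc = centered[:, 0] @ centered[:, 1] / n
    half_trace = 0.5 * (crr + ccc)
    disc = math.sqrt(max(0.25 * (crr - ccc) ** 2 + crc * crc, 0.0))
    lam1 = half_trace + disc
    lam2 = max(half_trace - disc, 0.0)
    major = 4.0 * math.sqrt(lam1)
    minor = 4.0 * math.sqrt(lam2)
    # principal eigenvector of [[crr, crc], [crc, ccc]] for eigenvalue lam1:
    # (lam1 - ccc, crc), falling back to (crc, lam1 - crr) when degenerate
    vr, vc = lam1 - ccc, crc
    if vr == 0.0 and vc == 0.0:
        vr, vc = crc, lam1 - crr
    if vr == 0.0 and vc == 0.0:  # isotropic component
        theta = 0.0
    else:
        theta = math.atan2(vr, vc)
    # fold into (-pi/2, pi/2]
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    return major, minor, theta


def measure_components(mask: np.ndarray, image_id: str | None = None) -> pd.DataFrame:
    """One row per 8-connected component: area, centroid, ellipse axes.

    Returns a DataFrame with :data:`COMPONENT_COLUMNS` (plus ``image_id``
    when given); ``df.attrs['image_shape']`` records the mask shape.
    """
    labels, count = label_components(mask)
    rows = []
    for lab in range(1, count + 1):
        coords = np.argwhere(labels == lab)
        major, minor, theta = ellipse_axes(coords)
        centroid = coords.mean(axis=0)
        rows.append(
            {
                "label": lab,
                "area_px": int(coords.shape[0]),
                "centroid_row": float(centroid[0]),
                "centroid_col": float(centroid[1]),
                "major_axis_px": major,
                "minor_axis_px": minor,
                "orientation_rad": theta,
            }
        )
    frame = pd.DataFrame(rows, columns=list(COMPONENT_COLUMNS))
    if image_id is not None:
        frame.insert(0, "image_id", image_id)
    frame.attrs["image_shape"] = tuple(np.asarray(mask).shape)
    return frame


def match_to_reference(
    components: pd.DataFrame,
    reference: pd.DataFrame,
    position_scale: float = 1.0,
    max_distance: float | None = None,
) -> tuple[pd.DataFrame, list[int], list[int]]:
    """Greedily pair components with reference fruits by centroid distance.

    Reference ``approx_row``/``approx_col`` positions are multiplied by
    ``position_scale`` to bring them to the mask's working resolution.
    Pairs are accepted nearest-first under a gate ``max_distance``
    (default: 1.5x the median component minor axis).  An exact distance tie
    between two references for one component raises
    :class:`AmbiguousMatchError`.

    Returns
    -------
    (matched, unmatched_component_labels, unmatched_reference_fruit_ids)
    where *matched* joins the component columns with the reference columns.
    """
    if len(components) == 0 or len(reference) == 0:
        return (
            pd.DataFrame(),
            list(components["label"]) if len(components) else [],
            list(reference["fruit_id"]) if len(reference) else [],
        )
    if max_distance is None:
        max_distance = 1.5 * float(components["minor_axis_px"].median())
    comp_pos = components[["centroid_row", "centroid_col"]].to_numpy(float)
    ref_pos = reference[["approx_row", "approx_col"]].to_numpy(float) * position_scale
    dist = np.linalg.norm(comp_pos[:, None, :] - ref_pos[None, :, :], axis=2)

    within = dist <= max_distance
    for ci in range(dist.shape[0]):
        cands = np.flatnonzero(within[ci])
        if cands.size >= 2:
            d = np.sort(dist[ci, cands])
            if math.isclose(d[0], d[1], rel_tol=0.0, abs_tol=1e-9):
                tied = cands[np.isclose(dist[ci, cands], d[0], atol=1e-9)]
                ids = reference.iloc[tied]["fruit_id"].tolist()
                raise AmbiguousMatchError(
                    f"component label {components.iloc[ci]['label']} is equidistant "
                    f"from reference fruits {ids} (distance {d[0]:.3f} px)"
                )

    order = np.argsort(dist, axis=None, kind="stable")
    used_c: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        ci, ri = np.unravel_index(flat, dist.shape)
        if dist[ci, ri] > max_distance:
            break
        if ci in used_c or ri in used_r:
            continue
        used_c.add(int(ci))
        used_r.add(int(ri))
        pairs.append((int(ci), int(ri)))

    comp_part = components.iloc[[p[0] for p in pairs]].reset_index(drop=True)
    ref_part = reference.iloc[[p[1] for p in pairs]].reset_index(drop=True)
    ref_part = ref_part.drop(
        columns=[c for c in ("image_id",) if c in comp_part.columns],
        errors="ignore",
    )
    collisions = {c: f"{c}_ref" for c in ref_part.columns if c in comp_part.columns}
    matched = pd.concat([comp_part, ref_part.rename(columns=collisions)], axis=1)
    unmatched_components = [
        int(components.iloc[i]["label"])
        for i in range(len(components))
        if i not in used_c
    ]
    unmatched_reference = [
        reference.iloc[i]["fruit_id"] for i in range(len(reference)) if i not in used_r
    ]
    return matched, unmatched_components, unmatched_reference
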