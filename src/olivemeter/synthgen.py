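"""Synthetic conveyor-mat scenes with known per-fruit ground truth.

A scene emulates a top-down photograph of olives spread on a bright white
plastic mat under halogen lighting: a near-achromatic bright background
with smooth low-frequency brightness folds, dark saturated elliptical
fruits from two colour families (dark-purple and green-brown), cast
shadows that are darker but — like real shadows on a white mat — keep the
background's low saturation (shadow pixels are produced by uniform RGB
scaling, which leaves hexcone saturation invariant), small specular
highlights inside the fruits, and Gaussian pixel noise.

Geometry defaults correspond to ~10 px/mm capture resolution
(``mm_per_px = 0.1``): after the pipeline's 40% down-scale a 50-px-radius
disk still contains any fruit, and fruits keep the minimum mutual
separation the segmentation method requires.

Fruit mass follows an affine law in projected ellipse area,
``mass = c1 * (pi/4 * major_mm * minor_mm) + c0 + N(0, sigma_g)`` —
matching the linearization the area->mass calibration assumes.  A
volume-proportional alternative (``mass_law_kind="volume"``,
mass ~ major * minor^2 rescaled to the same typical mass) is provided to
probe how the linear model degrades when that assumption is broken.

Everything is a pure function of the parameters and seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .raster_io import write_image, write_mask

__all__ = ["SceneParams", "SceneTruth", "PlacementError", "generate_scene", "generate_dataset"]

#: fruit colour families: base RGB of dark (ripe) and green-brown (unripe) olives
_COLOR_FAMILIES = {
    "dark-purple": (62, 34, 58),
    "green-brown": (98, 108, 46),
}


class PlacementError(RuntimeError):
    """Could not place the requested fruits under the separation constraint."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene (defaults = study conditions)."""

    image_size: tuple[int, int] = (1280, 1920)  # (rows, cols), capture resolution
    n_fruits: int = 10
    mm_per_px: float = 0.1  # capture resolution scale
    major_axis_mm: tuple[float, float] = (12.0, 22.0)
    minor_axis_mm: tuple[float, float] = (8.0, 15.0)
    color_family: str = "mixed"  # dark-purple | green-brown | mixed
    background_level: int = 235
    fold_amplitude: float = 12.0
    shadow_strength: float = 0.35
    highlight_count_per_fruit: int = 2
    min_separation_px: float = 280.0  # centre-to-centre, capture resolution
    noise_sigma: float = 2.0
    mass_law: tuple[float, float, float] = (0.015, 0.0, 0.05)  # c1 g/mm^2, c0 g, sigma g
    mass_law_kind: str = "area"  # area | volume
    seed: int = 0
    max_placement_attempts: int = 10_000

    def __post_init__(self) -> None:
        for name in ("major_axis_mm", "minor_axis_mm"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} range must be positive with min <= max")
        if self.min_separation_px < 0:
            raise ValueError("min_separation_px must be >= 0")
        if not 0.0 <= self.shadow_strength < 1.0:
            raise ValueError("shadow_strength must be in [0, 1)")
        if self.color_family not in (*_COLOR_FAMILIES, "mixed"):
            raise ValueError(f"unknown color_family {self.color_family!r}")
        if self.mass_law_kind not in ("area", "volume"):
            raise ValueError(f"unknown mass_law_kind {self.mass_law_kind!r}")

    def with_options(self, **kwargs) -> "SceneParams":
        return replace(self, **kwargs)


@dataclass
class SceneTruth:
    """Ground truth of one scene: the mask plus the per-fruit table.

    ``fruits`` columns: fruit_id, center_row, center_col, major_axis_mm,
    minor_axis_mm, major_axis_px, minor_axis_px, orientation_rad,
    painted_area_px, mass_g (axes in px at capture resolution).
    """

    mask: np.ndarray
    fruits: pd.DataFrame = field(repr=False)


def _ellipse_region(rows, cols, center, a, b, theta):
    """Boolean window + offsets of the ellipse with semi-axes a, b (px)."""
    cr, cc = center
    extent = int(np.ceil(max(a, b))) + 2
    r0, r1 = max(0, int(cr) - extent), min(rows, int(cr) + extent + 1)
    c0, c1 = max(0, int(cc) - extent), min(cols, int(cc) + extent + 1)
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    dr = rr - cr
    dc = cc_grid - cc
    u = dc * np.cos(theta) + dr * np.sin(theta)  # along major axis
    w = -dc * np.sin(theta) + dr * np.cos(theta)
    inside = (u / a) ** 2 + (w / b) ** 2 <= 1.0
    return inside, (r0, r1, c0, c1)


def _place_centers(rng, params: SceneParams, margin: float) -> np.ndarray:
    rows, cols = params.image_size
    lo_r, hi_r = margin, rows - margin
    lo_c, hi_c = margin, cols - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise PlacementError("image too small for the fruit size and margin")
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < params.n_fruits:
        if attempts >= params.max_placement_attempts:
            raise PlacementError(
                f"placed only {len(centers)}/{params.n_fruits} fruits after "
                f"{attempts} attempts (min_separation_px={params.min_separation_px})"
            )
        attempts += 1
        cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        if all(
            np.hypot(cand[0] - r, cand[1] - c) >= params.min_separation_px
            for r, c in centers
        ):
            centers.append(cand)
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def _fruit_mass(rng, params: SceneParams, major_mm, minor_mm) -> np.ndarray:
    c1, c0, sigma_g = params.mass_law
    area_mm2 = np.pi / 4.0 * major_mm * minor_mm
    if params.mass_law_kind == "area":
        mean = c1 * area_mm2 + c0
    else:
        # volume-like law rescaled so a mid-range fruit has the same mass
        # as under the area law
        mid_major = np.mean(params.major_axis_mm)
        mid_minor = np.mean(params.minor_axis_mm)
        ref_area_mass = c1 * np.pi / 4.0 * mid_major * mid_minor + c0
        ref_volume = mid_major * mid_minor**2
        mean = ref_area_mass * (major_mm * minor_mm**2) / ref_volume
    noise = rng.normal(0.0, sigma_g, size=np.shape(mean)) if sigma_g > 0 else 0.0
    return np.maximum(mean + noise, 0.01)


def generate_scene(params: SceneParams | None = None) -> tuple[np.ndarray, SceneTruth]:
    """Render one scene; deterministic given ``params`` (including its seed)."""
    params = params or SceneParams()
    rng = np.random.default_rng(params.seed)
    rows, cols = params.image_size

    # fruit geometry
    major_mm = rng.uniform(*params.major_axis_mm, size=params.n_fruits)
    minor_hi = np.minimum(params.minor_axis_mm[1], major_mm)
    minor_mm = rng.uniform(params.minor_axis_mm[0], minor_hi)
    theta = rng.uniform(-np.pi / 2, np.pi / 2, size=params.n_fruits)
    a_px = major_mm / 2.0 / params.mm_per_px
    b_px = minor_mm / 2.0 / params.mm_per_px
    margin = params.major_axis_mm[1] / 2.0 / params.mm_per_px + 20.0
    centers = _place_centers(rng, params, margin)

    # background: bright near-achromatic mat with low-frequency folds
    bl = params.background_level
    base = np.array([bl, bl - 3, bl - 8], dtype=float)
    image = np.broadcast_to(base, (rows, cols, 3)).astype(float).copy()
    if params.fold_amplitude > 0:
        rr, cc = np.mgrid[0:rows, 0:cols]
        folds = np.zeros((rows, cols))
        weights = rng.dirichlet(np.ones(3))
        for k in range(3):
            # folds are broad relative to fruit scale: after the 40% down-scale
            # their wavelength stays well above the 50-px background disk, so
            # the background estimate can track them
            wavelength = rng.uniform(1500.0, 3000.0)
            direction = rng.uniform(0.0, np.pi)
            phase = rng.uniform(0.0, 2 * np.pi)
            proj = rr * np.sin(direction) + cc * np.cos(direction)
            folds += weights[k] * np.cos(2 * np.pi * proj / wavelength + phase)
        image += (params.fold_amplitude * folds)[..., None]

    # cast shadows: uniform RGB scaling (saturation-invariant), offset along
    # a single per-scene light direction, slightly larger than the fruit
    if params.shadow_strength > 0:
        light_dir = rng.uniform(0.0, 2 * np.pi)
        shadow = np.zeros((rows, cols), dtype=bool)
        for i in range(params.n_fruits):
            offset = 0.30 * b_px[i] + 6.0
            center = (
                centers[i, 0] + offset * np.sin(light_dir),
                centers[i, 1] + offset * np.cos(light_dir),
            )
            inside, (r0, r1, c0, c1) = _ellipse_region(
                rows, cols, center, 1.08 * a_px[i], 1.08 * b_px[i], theta[i]
            )
            shadow[r0:r1, c0:c1] |= inside
        image[shadow] *= 1.0 - params.shadow_strength

    # fruits: solid saturated dark ellipses with per-fruit colour jitter
    mask = np.zeros((rows, cols), dtype=np.uint8)
    painted_area = np.zeros(params.n_fruits, dtype=int)
    if params.color_family == "mixed":
        families = rng.choice(list(_COLOR_FAMILIES), size=params.n_fruits)
    else:
        families = np.full(params.n_fruits, params.color_family)
    for i in range(params.n_fruits):
        color = np.array(_COLOR_FAMILIES[families[i]], dtype=float)
        color = np.clip(color + rng.uniform(-10, 10, size=3), 0, 180)
        inside, (r0, r1, c0, c1) = _ellipse_region(
            rows, cols, centers[i], a_px[i], b_px[i], theta[i]
        )
        image[r0:r1, c0:c1][inside] = color
        mask[r0:r1, c0:c1][inside] = 255
        painted_area[i] = int(np.count_nonzero(inside))

        # specular highlights: small bright low-saturation blobs well inside
        for _ in range(params.highlight_count_per_fruit):
            t = rng.uniform(0.0, 2 * np.pi)
            rho = rng.uniform(0.0, 0.55)
            hc = (
                centers[i, 0] + rho * (a_px[i] * np.cos(t) * np.sin(theta[i]) - b_px[i] * np.sin(t) * np.cos(theta[i])),
                centers[i, 1] + rho * (a_px[i] * np.cos(t) * np.cos(theta[i]) + b_px[i] * np.sin(t) * np.sin(theta[i])),
            )
            h_r = rng.uniform(4.0, 9.0)
            blob, (hr0, hr1, hc0, hc1) = _ellipse_region(rows, cols, hc, h_r, h_r, 0.0)
            blob &= mask[hr0:hr1, hc0:hc1] == 255
            region = image[hr0:hr1, hc0:hc1]
            region[blob] = 0.15 * region[blob] + 0.85 * np.array([250.0, 248.0, 245.0])

    if params.noise_sigma > 0:
        image += rng.normal(0.0, params.noise_sigma, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    mass_g = _fruit_mass(rng, params, major_mm, minor_mm)
    fruits = pd.DataFrame(
        {
            "fruit_id": np.arange(1, params.n_fruits + 1),
            "center_row": centers[:, 0],
            "center_col": centers[:, 1],
            "major_axis_mm": major_mm,
            "minor_axis_mm": minor_mm,
            "major_axis_px": 2 * a_px,
            "minor_axis_px": 2 * b_px,
            "orientation_rad": theta,
            "painted_area_px": painted_area,
            "mass_g": mass_g,
        }
    )
    return image, SceneTruth(mask=mask, fruits=fruits)


def generate_dataset(
    n_images: int,
    params: SceneParams | None = None,
    out_dir: str | os.PathLike = ".",
) -> dict:
    """Write ``n_images`` scenes, their truth masks and a reference CSV.

    Scene ``i`` uses seed ``params.seed + i``.  Outputs, all under
    ``out_dir``: ``image_XXX.png``, ``truth_XXX.png``, ``reference.csv``
    (one row per fruit in the reference-table schema, with the painted
    pixel ground truth as extra columns) and ``manifest.json`` recording
    the exact parameters, so the dataset can be regenerated bit-identically.
    """
    params = params or SceneParams()
    os.makedirs(out_dir, exist_ok=True)
    records = []
    files = []
    for i in range(n_images):
        image, truth = generate_scene(params.with_options(seed=params.seed + i))
        image_id = f"image_{i:03d}"
        image_name = f"{image_id}.png"
        mask_name = f"truth_{i:03d}.png"
        try:
            write_image(image, os.path.join(out_dir, image_name))
            write_mask(truth.mask, os.path.join(out_dir, mask_name))
        except IOError as exc:
            raise IOError(f"failed writing scene {image_id}: {exc}") from exc
        files.append({"image": image_name, "truth": mask_name, "image_id": image_id})
        table = truth.fruits.rename(
            columns={"center_row": "approx_row", "center_col": "approx_col"}
        )
        table.insert(0, "image_id", image_id)
        records.append(table)
    reference = pd.concat(records, ignore_index=True)
    reference.to_csv(os.path.join(out_dir, "reference.csv"), index=False)
    manifest = {
        "n_images": n_images,
        "params": asdict(params),
        "files": files,
        "reference": "reference.csv",
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
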