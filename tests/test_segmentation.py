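"""Unit and property tests of the segmentation pipeline stages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from olivemeter import segmentation as seg
from olivemeter import synthgen

from .conftest import SMALL_SCENE_PARAMS, brute_opening, brute_otsu

CONFIG = seg.SegmentationConfig()

channels = hnp.arrays(
    dtype=np.uint8, shape=st.tuples(st.integers(4, 24), st.integers(4, 24))
)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_constant_image_stays_constant_at_target_size():
    image = np.full((100, 100, 3), (90, 120, 200), dtype=np.uint8)
    out = seg.preprocess(image, CONFIG)
    assert out.shape == (40, 40, 3)
    assert (out == np.array([90, 120, 200], dtype=np.uint8)).all()


def test_preprocess_identity_limit():
    """scale 1.0 with a near-delta kernel leaves the image unchanged."""
    rng = np.random.default_rng(1)
    image = rng.integers(0, 256, (20, 30, 3), dtype=np.uint8)
    config = seg.SegmentationConfig(scale_factor=1.0, gaussian_sigma=1e-2)
    np.testing.assert_array_equal(seg.preprocess(image, config), image)


def test_preprocess_single_bright_pixel_matches_kernel_weights():
    """Direct convolution arithmetic: the response to a delta is the kernel."""
    image = np.zeros((11, 11, 3), dtype=np.uint8)
    image[5, 5] = 255
    config = seg.SegmentationConfig(scale_factor=1.0)
    out = seg.preprocess(image, config)
    ax = np.arange(-2, 3, dtype=float)
    dr, dc = np.meshgrid(ax, ax, indexing="ij")
    kernel = np.exp(-(dr**2 + dc**2) / (2 * 0.8**2))
    kernel /= kernel.sum()
    expected = np.clip(np.rint(kernel * 255), 0, 255).astype(np.uint8)
    np.testing.assert_array_equal(out[3:8, 3:8, 0], expected)
    assert (out[np.abs(np.arange(11) - 5) > 2][:, :, 0] == 0).all()


def test_preprocess_rejects_single_channel():
    with pytest.raises(TypeError):
        seg.preprocess(np.zeros((10, 10), dtype=np.uint8), CONFIG)


@pytest.mark.parametrize(
    "bad_kwargs",
    [dict(scale_factor=0.0), dict(scale_factor=1.5), dict(gaussian_sigma=0.0),
     dict(gaussian_kernel=4), dict(bg_disk_radius=0)],
)
def test_config_rejects_invalid_parameters(bad_kwargs):
    with pytest.raises(ValueError):
        seg.SegmentationConfig(**bad_kwargs)


# ---------------------------------------------------------------------------
# HSV split, inversion, fusion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rgb, expected_s, expected_v",
    [
        ((255, 0, 0), 255, 255),  # saturated primary
        ((128, 128, 128), 0, 128),  # achromatic
        ((64, 128, 192), 170, 192),  # round(255*(192-64)/192) = 170
        ((0, 0, 0), 0, 0),  # black: S defined as 0
    ],
)
def test_split_hsv_hexcone_values(rgb, expected_s, expected_v):
    image = np.full((2, 2, 3), rgb, dtype=np.uint8)
    s, v = seg.split_hsv(image)
    assert (s == expected_s).all()
    assert (v == expected_v).all()


@settings(derandomize=True, max_examples=30)
@given(channels)
def test_invert_value_is_an_involution(v):
    np.testing.assert_array_equal(seg.invert_value(seg.invert_value(v)), v)
    assert seg.invert_value(np.zeros_like(v)).max() == 255 or v.size == 0


def test_fuse_channels_saturating_addition():
    s = np.array([[10, 200, 0]], dtype=np.uint8)
    v_inv = np.array([[20, 100, 0]], dtype=np.uint8)
    np.testing.assert_array_equal(
        seg.fuse_channels(s, v_inv), np.array([[30, 255, 0]], dtype=np.uint8)
    )


def test_fuse_channels_white_background_maps_to_zero():
    white = np.full((3, 3, 3), 255, dtype=np.uint8)
    s, v = seg.split_hsv(white)
    assert (seg.fuse_channels(s, seg.invert_value(v)) == 0).all()


def test_fuse_channels_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shape mismatch"):
        seg.fuse_channels(np.zeros((2, 2), np.uint8), np.zeros((3, 3), np.uint8))


# ---------------------------------------------------------------------------
# background estimation / subtraction
# ---------------------------------------------------------------------------

def test_opening_preserves_constant_images():
    image = np.full((40, 40), 77, dtype=np.uint8)
    np.testing.assert_array_equal(seg.estimate_background(image, 5), image)


def test_opening_removes_bright_blob_smaller_than_element():
    image = np.full((64, 64), 30, dtype=np.uint8)
    rr, cc = np.mgrid[0:64, 0:64]
    image[(rr - 32) ** 2 + (cc - 32) ** 2 <= 8**2] = 200
    background = seg.estimate_background(image, 12)
    assert (background == 30).all()
    high_contrast = seg.subtract_background(image, background)
    assert high_contrast[32, 32] == 170
    assert high_contrast[0, 0] == 0


@pytest.mark.parametrize("radius", [1, 3, 7])
def test_opening_matches_brute_force_oracle(radius):
    rng = np.random.default_rng(radius)
    image = rng.integers(0, 256, (48, 48), dtype=np.uint8)
    np.testing.assert_array_equal(
        seg.estimate_background(image, radius), brute_opening(image, radius)
    )


@settings(derandomize=True, max_examples=20)
@given(channels, st.integers(1, 6))
def test_opening_is_anti_extensive(image, radius):
    assert (seg.estimate_background(image, radius) <= image).all()


def test_subtract_background_floors_at_zero_and_identity_cases():
    image = np.array([[10, 50]], dtype=np.uint8)
    np.testing.assert_array_equal(seg.subtract_background(image, image), [[0, 0]])
    np.testing.assert_array_equal(
        seg.subtract_background(image, np.zeros_like(image)), image
    )
    np.testing.assert_array_equal(
        seg.subtract_background(image, np.array([[20, 20]], dtype=np.uint8)),
        [[0, 30]],
    )


# ---------------------------------------------------------------------------
# Otsu thresholding and binarization
# ---------------------------------------------------------------------------

def test_otsu_two_delta_histogram_returns_smallest_tie():
    image = np.repeat(np.array([50, 200], dtype=np.uint8), 100)
    assert seg.otsu_threshold(image) == 50


@pytest.mark.parametrize("seed", range(8))
def test_otsu_equals_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    if seed % 2:  # bimodal mixture
        image = np.concatenate(
            [rng.normal(60, 12, 900), rng.normal(190, 18, 400)]
        ).clip(0, 255).astype(np.uint8)
    else:
        image = rng.integers(0, 256, 1500, dtype=np.uint8)
    assert seg.otsu_threshold(image) == brute_otsu(image)


def test_otsu_constant_image_is_degenerate():
    with pytest.raises(seg.DegenerateHistogramError):
        seg.otsu_threshold(np.full((10, 10), 42, dtype=np.uint8))


def test_binarize_uses_strict_inequality():
    assert (seg.binarize(np.zeros((3, 3), np.uint8), 0) == 0).all()
    assert (seg.binarize(np.full((3, 3), 255, np.uint8), 0) == 255).all()
    image = np.repeat(np.array([50, 200], dtype=np.uint8), 5).reshape(2, 5)
    mask = seg.binarize(image, 50)
    np.testing.assert_array_equal(mask, np.where(image == 200, 255, 0))


# ---------------------------------------------------------------------------
# mask postprocessing
# ---------------------------------------------------------------------------

def test_clean_mask_removes_isolated_pixel():
    mask = np.zeros((20, 20), dtype=np.uint8)
    mask[10, 10] = 255
    assert not seg.clean_mask(mask, 3).any()


def test_clean_mask_rounds_square_corners_like_oracle():
    mask = np.zeros((64, 64), dtype=np.uint8)
    mask[7:57, 7:57] = 255
    opened = seg.clean_mask(mask, 3)
    np.testing.assert_array_equal(opened, brute_opening(mask, 3))
    assert (opened[20:44, 20:44] == 255).all()  # interior untouched


@settings(derandomize=True, max_examples=20)
@given(hnp.arrays(dtype=np.bool_, shape=st.tuples(st.integers(4, 20), st.integers(4, 20))))
def test_clean_mask_output_is_subset_of_input(fg):
    mask = np.where(fg, 255, 0).astype(np.uint8)
    cleaned = seg.clean_mask(mask, 2)
    assert not np.any(cleaned & ~mask)


def test_fill_holes_fills_enclosed_background():
    mask = np.zeros((21, 21), dtype=np.uint8)
    rr, cc = np.mgrid[0:21, 0:21]
    dist2 = (rr - 10) ** 2 + (cc - 10) ** 2
    mask[(dist2 <= 8**2) & (dist2 >= 3**2)] = 255  # ring, interior hole
    filled = seg.fill_holes(mask)
    assert (filled[dist2 <= 8**2] == 255).all()
    assert (filled[dist2 > 8**2] == mask[dist2 > 8**2]).all()


def test_fill_holes_leaves_border_open_concavity():
    """A C-shape's cavity is 4-connected to the border and must stay open."""
    mask = np.zeros((15, 15), dtype=np.uint8)
    mask[2:13, 2:13] = 255
    mask[5:10, 5:15] = 0  # slot open to the right border
    from scipy import ndimage

    oracle = np.where(ndimage.binary_fill_holes(mask > 0), 255, 0).astype(np.uint8)
    filled = seg.fill_holes(mask)
    np.testing.assert_array_equal(filled, oracle)
    np.testing.assert_array_equal(filled, mask)


@settings(derandomize=True, max_examples=25)
@given(hnp.arrays(dtype=np.bool_, shape=st.tuples(st.integers(4, 24), st.integers(4, 24))))
def test_fill_holes_matches_border_flood_fill_oracle(fg):
    from scipy import ndimage

    mask = np.where(fg, 255, 0).astype(np.uint8)
    filled = seg.fill_holes(mask)
    oracle = np.where(ndimage.binary_fill_holes(fg), 255, 0).astype(np.uint8)
    np.testing.assert_array_equal(filled, oracle)
    # extensive and idempotent
    assert not np.any(mask & ~filled)
    np.testing.assert_array_equal(seg.fill_holes(filled), filled)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def test_segment_finds_every_fruit(small_scene, small_scene_mask):
    from olivemeter.features import label_components

    _, truth = small_scene
    _, count = label_components(small_scene_mask)
    assert count == len(truth.fruits)


def test_segment_default_scene_component_count():
    from olivemeter.features import label_components

    image, truth = synthgen.generate_scene(synthgen.SceneParams(seed=7))
    mask = seg.segment(image)
    _, count = label_components(mask)
    assert count == len(truth.fruits) == 10


def test_segment_clean_empty_mat_yields_empty_mask(caplog):
    """A fruit-free mat in the noise-free limit hits the degenerate-histogram
    path and returns an all-background mask with a logged warning."""
    params = SMALL_SCENE_PARAMS.with_options(
        n_fruits=0, noise_sigma=0.0, fold_amplitude=0.0, shadow_strength=0.0
    )
    image, _ = synthgen.generate_scene(params)
    with caplog.at_level("WARNING", logger="olivemeter.segmentation"):
        mask = seg.segment(image)
    assert not mask.any()
    assert any("degenerate" in record.message for record in caplog.records)


def test_segment_is_mirror_equivariant(small_scene, small_scene_mask):
    image, _ = small_scene
    mirrored = seg.segment(image[:, ::-1].copy())
    np.testing.assert_array_equal(mirrored[:, ::-1], small_scene_mask)


def test_segment_output_has_downscaled_shape(small_scene, small_scene_mask):
    image, _ = small_scene
    assert small_scene_mask.shape == (
        round(image.shape[0] * 0.4),
        round(image.shape[1] * 0.4),
    )
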