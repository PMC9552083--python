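"""Local keypoint descriptors and the color auto-correlogram (vs an all-pairs
brute-force oracle)."""

import numpy as np
import pytest

import histofuse as hf
from histofuse.appearance_features import (ColorPalette, DISTANCES,
                                           autocorrelogram_from_labels,
                                           color_autocorrelogram,
                                           extract_local_descriptors,
                                           uniform_quantize)
from histofuse.datatypes import CapabilityError


# ------------------------------------------------------------ local features

def test_descriptor_widths_per_method(malignant_image):
    image, _ = malignant_image
    assert extract_local_descriptors(image, "sift").width == 128
    assert extract_local_descriptors(image, "orb").width == 32
    surf = extract_local_descriptors(image, "surf", allow_surf_fallback=True)
    assert surf.width == 64


def test_uniform_image_has_no_keypoints():
    flat = np.full((224, 224, 3), 180, np.uint8)
    for method in ("sift", "orb"):
        assert len(extract_local_descriptors(flat, method)) == 0


def test_unknown_method_and_surf_capability_error(malignant_image):
    image, _ = malignant_image
    with pytest.raises(ValueError, match="unknown method"):
        extract_local_descriptors(image, "brisk")
    with pytest.raises(CapabilityError, match="allow_surf_fallback"):
        extract_local_descriptors(image, "surf")


def test_surf_fallback_pools_sift_pairs(malignant_image):
    image, _ = malignant_image
    sift = extract_local_descriptors(image, "sift").values
    surf = extract_local_descriptors(image, "surf", allow_surf_fallback=True).values
    np.testing.assert_allclose(
        surf, sift.reshape(-1, 16, 4, 2).sum(axis=3).reshape(-1, 64))


# ------------------------------------------------------------- correlogram

def brute_correlogram(labels, n_colors, distances):
    """Independent all-pairs enumeration oracle."""
    h, w = labels.shape
    out = np.zeros((n_colors, len(distances)))
    for di, d in enumerate(distances):
        same = np.zeros(n_colors)
        total = np.zeros(n_colors)
        for y in range(h):
            for x in range(w):
                c = labels[y, x]
                for dy in range(-d, d + 1):
                    for dx in range(-d, d + 1):
                        if max(abs(dy), abs(dx)) != d:
                            continue
                        y2, x2 = y + dy, x + dx
                        if 0 <= y2 < h and 0 <= x2 < w:
                            total[c] += 1
                            same[c] += labels[y2, x2] == c
        out[:, di] = np.where(total > 0, same / np.maximum(total, 1), 0.0)
    return out.ravel()


def test_correlogram_matches_brute_force_on_random_images():
    rng = np.random.default_rng(10)
    for _ in range(20):
        labels = rng.integers(0, 10, (16, 16))
        got = autocorrelogram_from_labels(labels, 10, DISTANCES)
        expected = brute_correlogram(labels, 10, DISTANCES)
        np.testing.assert_allclose(got, expected, atol=1e-12)


def test_uniform_image_is_perfectly_autocorrelated():
    flat = np.full((32, 32, 3), 200, np.uint8)
    feat = color_autocorrelogram(flat)
    by_color = feat.reshape(10, 5)
    color = uniform_quantize(flat)[0, 0]
    assert np.allclose(by_color[color], 1.0)
    mask = np.ones(10, bool)
    mask[color] = False
    assert np.allclose(by_color[mask], 0.0)


def test_vertical_stripes_match_pair_ratio():
    labels = np.tile([0, 1], (4, 2))  # 4x4 alternating width-1 stripes
    got = autocorrelogram_from_labels(labels, 2, (1,))
    np.testing.assert_allclose(got, brute_correlogram(labels, 2, (1,)))


def test_output_shape_and_range(benign_image):
    feat = color_autocorrelogram(benign_image[0])
    assert feat.shape == (50,)
    assert (feat >= 0).all() and (feat <= 1).all()


def test_absent_colors_contribute_zero():
    labels = np.zeros((16, 16), int)  # only color 0 present
    feat = autocorrelogram_from_labels(labels, 10, DISTANCES).reshape(10, 5)
    assert np.allclose(feat[1:], 0.0)


def test_too_small_image_raises():
    tiny = np.zeros((8, 8, 3), np.uint8)
    with pytest.raises(ValueError, match="distance"):
        color_autocorrelogram(tiny)
    with pytest.raises(ValueError):
        color_autocorrelogram(np.zeros((32, 32, 3), np.uint8),
                              distances=(3, 1, 5))


def test_palette_quantization_and_round_trip(tmp_path, benign_image,
                                             malignant_image):
    palette = ColorPalette.fit([benign_image[0], malignant_image[0]], seed=0)
    labels = palette.quantize(benign_image[0].pixels)
    assert labels.min() >= 0 and labels.max() < 10
    palette.to_json(tmp_path / "pal.json")
    loaded = ColorPalette.from_json(tmp_path / "pal.json")
    np.testing.assert_allclose(loaded.centroids, palette.centroids)


def test_stain_dimming_moves_adaptive_correlogram_less_than_raw_histogram(
        benign_image):
    """Operational stain robustness: under a global multiplicative stain
    shift, the auto-correlogram computed against a freshly fitted palette
    (the pipeline's stain-handling route) moves less than a raw color
    histogram quantized against the stale palette."""
    image = benign_image[0]
    shifted = np.clip(image.pixels.astype(float) * 0.92, 0, 255).astype(np.uint8)
    pal_a = ColorPalette.fit([image], seed=0)
    pal_b = ColorPalette.fit([hf.LabeledImage(shifted, image.label, "s")], seed=0)
    f_a = color_autocorrelogram(image, palette=pal_a)
    f_b = color_autocorrelogram(shifted, palette=pal_b)
    corr_change = np.abs(f_a - f_b).max()
    lab_fixed_a = pal_a.quantize(image.pixels)
    lab_fixed_b = pal_a.quantize(shifted)
    h_a = np.bincount(lab_fixed_a.ravel(), minlength=10) / lab_fixed_a.size
    h_b = np.bincount(lab_fixed_b.ravel(), minlength=10) / lab_fixed_b.size
    hist_change = np.abs(h_a - h_b).max()
    assert corr_change < hist_change
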