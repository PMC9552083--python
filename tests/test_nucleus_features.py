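"""Watershed segmentation, GLCM statistics (vs brute-force pair counting) and
Fourier contour descriptors."""

import numpy as np
import pytest
from skimage.measure import regionprops

from histofuse.nucleus_features import (contour_fourier_descriptor,
                                        glcm_statistics, nucleus_descriptors,
                                        segment_nuclei)
from histofuse.synthetic_data import render_tissue

# ---------------------------------------------------------- brute-force oracle

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(patch, levels, distance, angle_deg):
    """Symmetric normalized co-occurrence matrix by explicit pair enumeration."""
    dy, dx = (o * distance for o in _OFFSETS[angle_deg])
    counts = np.zeros((levels, levels))
    h, w = patch.shape
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w:
                counts[patch[y, x], patch[y2, x2]] += 1
    counts = counts + counts.T
    return counts / counts.sum()


def brute_stats(P):
    L = P.shape[0]
    i, j = np.indices((L, L))
    mu_i = (P * i).sum()
    mu_j = (P * j).sum()
    var_i = (P * (i - mu_i) ** 2).sum()
    var_j = (P * (j - mu_j) ** 2).sum()
    corr = (1.0 if var_i <= 0 or var_j <= 0
            else (P * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
    nz = P[P > 0]
    return np.array([(P**2).sum(), (P * (i - j) ** 2).sum(),
                     (P * np.abs(i - j)).sum(), (P / (1 + (i - j) ** 2)).sum(),
                     corr, -(nz * np.log(nz)).sum()])


def test_glcm_matches_brute_force_on_random_patches():
    rng = np.random.default_rng(42)
    for _ in range(50):
        patch = rng.integers(0, 4, (8, 8))
        expected = np.mean([brute_stats(brute_glcm(patch, 4, 1, a))
                            for a in (0, 45, 90, 135)], axis=0)
        got = glcm_statistics(patch, levels=4, distance=1)
        np.testing.assert_allclose(got, expected, atol=1e-10)


def test_glcm_oracle_matrix_is_normalized():
    rng = np.random.default_rng(7)
    patch = rng.integers(0, 4, (8, 8))
    for a in (0, 45, 90, 135):
        assert abs(brute_glcm(patch, 4, 1, a).sum() - 1.0) < 1e-12


def test_glcm_worked_two_by_two_example():
    # [[0,1],[0,1]] at d=1, 0 deg: P(0,1)=P(1,0)=0.5
    stats = glcm_statistics([[0, 1], [0, 1]], levels=2, distance=1,
                            angles_deg=(0,))
    energy, contrast, dissimilarity, homogeneity, _, _ = stats
    assert contrast == pytest.approx(1.0)
    assert dissimilarity == pytest.approx(1.0)
    assert homogeneity == pytest.approx(0.5)
    assert energy == pytest.approx(0.5)


def test_glcm_constant_patch():
    stats = glcm_statistics(np.full((8, 8), 3), levels=16, distance=1)
    energy, contrast, dissimilarity, homogeneity, correlation, entropy = stats
    assert energy == pytest.approx(1.0)
    assert contrast == pytest.approx(0.0)
    assert dissimilarity == pytest.approx(0.0)
    assert homogeneity == pytest.approx(1.0)
    assert correlation == pytest.approx(1.0)  # zero-variance convention
    assert entropy == pytest.approx(0.0)


def test_glcm_checkerboard_has_higher_contrast_than_constant():
    checker = np.indices((8, 8)).sum(axis=0) % 2
    c_checker = glcm_statistics(checker, levels=2, distance=1)[1]
    c_const = glcm_statistics(np.zeros((8, 8), int), levels=2, distance=1)[1]
    assert c_checker > c_const


def test_glcm_preconditions():
    with pytest.raises(ValueError):
        glcm_statistics([[0]], levels=2, distance=1)
    with pytest.raises(ValueError):
        glcm_statistics(np.zeros((4, 4), int), levels=2, distance=4)
    with pytest.raises(ValueError):
        glcm_statistics(np.zeros((4, 4), int), levels=1, distance=1)


# ---------------------------------------------------------- Fourier descriptor

def _ellipse(n, cy=50.0, cx=60.0, ry=20.0, rx=30.0):
    t = np.linspace(0, 2 * np.pi, n + 1)
    return np.stack([cy + ry * np.sin(t), cx + rx * np.cos(t)], axis=1)


def test_descriptor_length_is_sixty_with_and_without_padding():
    assert len(contour_fourier_descriptor(_ellipse(100))) == 60
    assert len(contour_fourier_descriptor(_ellipse(40))) == 60
    assert len(contour_fourier_descriptor(_ellipse(3))) == 60


def test_translation_changes_only_the_dc_coefficient():
    a = contour_fourier_descriptor(_ellipse(100))
    b = contour_fourier_descriptor(_ellipse(100) + 10.0)
    diff = np.abs(a - b)
    changed = np.where(diff > 1e-9)[0]
    assert list(changed) == [30]  # DC sits at the center of the 60 bins


def test_scaling_multiplies_all_magnitudes_uniformly():
    a = contour_fourier_descriptor(_ellipse(80))
    b = contour_fourier_descriptor(_ellipse(80) * 1.7)
    nz = a > 1e-6
    ratios = b[nz] / a[nz]
    assert np.ptp(ratios) < 1e-6
    assert ratios[0] == pytest.approx(1.7, abs=1e-6)


def test_open_and_degenerate_contours_are_rejected():
    open_contour = _ellipse(50)[:-1]
    with pytest.raises(ValueError, match="closed"):
        contour_fourier_descriptor(open_contour)
    line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [0.0, 0.0]])
    with pytest.raises(ValueError, match="degenerate|collinear"):
        contour_fourier_descriptor(line)
    with pytest.raises(ValueError):
        contour_fourier_descriptor(np.array([[0.0, 0.0], [0.0, 0.0]]))


# ------------------------------------------------------------- segmentation

def test_ten_well_separated_nuclei_are_found_at_their_centers():
    centers = [(30 + 40 * r, 30 + 40 * c) for r in range(4) for c in range(4)][:10]
    pixels = render_tissue((224, 224), [(c, 5.0) for c in centers], seed=3,
                           noise_sd=2.0)
    regions = segment_nuclei(pixels)
    assert regions.n_regions == 10
    found = [p.centroid for p in regionprops(regions.labels)]
    for fy, fx in found:
        err = min(np.hypot(fy - y, fx - x) for y, x in centers)
        assert err <= 3.0


def test_uniform_white_image_has_no_nuclei():
    white = np.full((224, 224, 3), 255, np.uint8)
    assert segment_nuclei(white).n_regions == 0


def test_two_touching_nuclei_are_split():
    pixels = render_tissue((224, 224), [((100, 100), 8.0), ((100, 113), 8.0)],
                           seed=4, noise_sd=2.0)
    assert segment_nuclei(pixels).n_regions == 2


def test_descriptor_rows_align_with_regions(benign_image):
    image, _ = benign_image
    regions = segment_nuclei(image)
    texture, shape = nucleus_descriptors(image, regions)
    assert len(texture) == regions.n_regions == len(shape)
    assert texture.width == 6 and shape.width == 60


def test_empty_region_map_yields_empty_sets():
    white = np.full((64, 64, 3), 255, np.uint8)
    regions = segment_nuclei(white)
    texture, shape = nucleus_descriptors(white, regions)
    assert len(texture) == 0 and len(shape) == 0


def test_region_label_map_png_round_trip(tmp_path, benign_image):
    from histofuse.datatypes import RegionLabelMap
    regions = segment_nuclei(benign_image[0])
    regions.to_png(tmp_path / "labels.png")
    loaded = RegionLabelMap.from_png(tmp_path / "labels.png")
    np.testing.assert_array_equal(loaded.labels, regions.labels)


def test_descriptors_finite_on_seeded_images(gen224):
    import histofuse as hf
    for seed in range(10):
        label = "benign" if seed % 2 else "malignant"
        image, _ = hf.generate_image(label, gen224, seed=seed)
        regions = segment_nuclei(image)
        texture, shape = nucleus_descriptors(image, regions)
        assert np.isfinite(texture.values).all()
        assert np.isfinite(shape.values).all()
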