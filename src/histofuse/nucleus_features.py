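"""Nucleus segmentation and per-nucleus texture/shape descriptors.

Nuclei are the hematoxylin-dark blobs of the image.  They are segmented by a
classical marker-based watershed; each segmented nucleus then yields

* a 6-dimensional texture vector of gray-level co-occurrence matrix (GLCM)
  statistics -- energy, contrast, dissimilarity, homogeneity, correlation and
  entropy -- averaged over the four offsets 0/45/90/135 degrees, and
* a 60-dimensional shape vector of Fourier-coefficient magnitudes of the
  nucleus contour treated as a complex sequence x + iy.

The GLCM is the joint frequency of quantized gray-level pairs at a fixed
offset; its scalar statistics summarize local texture.  Low Fourier
frequencies of the contour encode gross shape, high ones boundary detail.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.feature import graycomatrix, peak_local_max
from skimage.filters import threshold_multiotsu
from skimage.measure import find_contours, regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed
from skimage.util import img_as_ubyte

from .datatypes import DescriptorSet, LabeledImage, RegionLabelMap

GLCM_STAT_NAMES = ("energy", "contrast", "dissimilarity", "homogeneity",
                   "correlation", "entropy")
N_SHAPE_COEFFS = 60
MIN_NUCLEUS_AREA = 9  # px
_GLCM_LEVELS = 16  # quantization used on 8-bit patches


def _as_pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, LabeledImage) else np.asarray(image)


def segment_nuclei(image) -> RegionLabelMap:
    """Watershed segmentation of nuclei (dark blobs) in an RGB image.

    Recipe: multi-Otsu (3 classes) on grayscale separates nuclei from
    stroma/lumen; the Euclidean distance transform of the nucleus mask is
    seeded at its local maxima (min separation 5 px) and flooded by watershed;
    regions below 9 px are discarded.  An image with no nuclei yields an empty
    map rather than an error.
    """
    pixels = _as_pixels(image)
    gray = rgb2gray(pixels)
    if gray.std() < 1e-3:
        return RegionLabelMap(np.zeros(gray.shape, dtype=np.int32))
    try:
        thresholds = threshold_multiotsu(gray, classes=3)
    except ValueError:  # too few distinct values for three classes
        return RegionLabelMap(np.zeros(gray.shape, dtype=np.int32))
    fg = gray < thresholds[0]
    fg = remove_small_objects(fg, max_size=MIN_NUCLEUS_AREA - 1)
    if not fg.any():
        return RegionLabelMap(np.zeros(gray.shape, dtype=np.int32))
    distance = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(distance, min_distance=5, labels=fg, exclude_border=False)
    markers = np.zeros(gray.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=fg)
    # drop runts, relabel consecutively
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= MIN_NUCLEUS_AREA]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return RegionLabelMap(remap[labels])


def glcm_statistics(gray_patch, levels: int = _GLCM_LEVELS, distance: int = 1,
                    angles_deg=(0, 45, 90, 135)) -> np.ndarray:
    """Six GLCM statistics of a quantized patch, averaged over offsets.

    ``gray_patch`` holds integers in ``[0, levels)``.  For each direction the
    co-occurrence matrix is made symmetric and normalized to sum to 1, the six
    statistics are computed, and the per-direction values are averaged.
    Entropy uses the natural logarithm; the correlation of a zero-variance
    (constant) patch is defined as 1.0.
    """
    patch = np.asarray(gray_patch)
    if patch.ndim != 2 or min(patch.shape) < 2:
        raise ValueError("patch must be 2-D and at least 2x2")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if distance < 1 or distance >= min(patch.shape):
        raise ValueError("distance must be >= 1 and smaller than the patch side")
    if patch.min() < 0 or patch.max() >= levels:
        raise ValueError("patch values must lie in [0, levels)")
    angles = np.deg2rad(angles_deg)
    glcm = graycomatrix(patch.astype(np.uint8), [distance], angles,
                        levels=levels, symmetric=True, normed=True)
    stats = np.array([_glcm_stats_single(glcm[:, :, 0, a]) for a in range(len(angles))])
    return stats.mean(axis=0)


def _glcm_stats_single(P: np.ndarray) -> np.ndarray:
    levels = P.shape[0]
    i, j = np.indices((levels, levels))
    diff = i - j
    energy = float((P**2).sum())
    contrast = float((P * diff**2).sum())
    dissimilarity = float((P * np.abs(diff)).sum())
    homogeneity = float((P / (1.0 + diff**2)).sum())
    mu_i = float((P * i).sum())
    mu_j = float((P * j).sum())
    var_i = float((P * (i - mu_i) ** 2).sum())
    var_j = float((P * (j - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0  # a constant patch is perfectly self-correlated
    else:
        correlation = float((P * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
    nz = P[P > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return np.array([energy, contrast, dissimilarity, homogeneity, correlation, entropy])


def contour_fourier_descriptor(contour_points, n_coeffs: int = N_SHAPE_COEFFS) -> np.ndarray:
    """Fourier-magnitude shape descriptor of a closed contour.

    The contour (first point repeated at the end) is read as the complex
    sequence ``x + iy``, discrete-Fourier transformed, and the zero-frequency
    component shifted to the center of the spectrum.  The ``n_coeffs`` central
    magnitudes form the descriptor; contours with fewer frequency bins are
    padded at both ends with their outermost (highest-frequency) magnitudes,
    any odd remainder going to the high end.
    """
    pts = np.asarray(contour_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be an (n, 2) point array")
    if not np.allclose(pts[0], pts[-1]):
        raise ValueError("contour must be closed (first point == last point)")
    pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("contour must have at least 3 distinct points")
    x, y = pts[:, 1], pts[:, 0]
    area2 = np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area2 < 1e-9:
        raise ValueError("degenerate (zero-area / collinear) contour")
    spectrum = np.fft.fftshift(np.fft.fft(x + 1j * y))
    mag = np.abs(spectrum)
    n = len(mag)
    if n >= n_coeffs:
        dc = n // 2
        out = mag[dc - n_coeffs // 2: dc + (n_coeffs + 1) // 2]
    else:
        deficit = n_coeffs - n
        left = deficit // 2
        out = np.concatenate([np.full(left, mag[0]), mag,
                              np.full(deficit - left, mag[-1])])
    return out.astype(float)


def region_contour(mask: np.ndarray) -> np.ndarray:
    """Longest closed iso-contour of a boolean region mask (padded to close)."""
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise ValueError("region has no contour")
    return max(contours, key=len) - 1.0  # undo the pad offset


def nucleus_descriptors(image, regions: RegionLabelMap) -> tuple[DescriptorSet, DescriptorSet]:
    """Per-nucleus texture (n x 6) and shape (n x 60) descriptor sets.

    Rows are aligned by region id.  The texture patch is the gray bounding box
    of the region quantized to 16 levels; the shape contour is the region's
    boundary.  An empty region map yields two empty sets.
    """
    pixels = _as_pixels(image)
    gray = img_as_ubyte(rgb2gray(pixels))
    quantized = gray // (256 // _GLCM_LEVELS)
    texture_rows, shape_rows = [], []
    for prop in regionprops(regions.labels):
        y0, x0, y1, x1 = prop.bbox
        patch = quantized[y0:y1, x0:x1]
        if min(patch.shape) < 2:  # degenerate sliver: pad to a 2x2 patch
            patch = np.pad(patch, ((0, max(0, 2 - patch.shape[0])),
                                   (0, max(0, 2 - patch.shape[1]))), mode="edge")
        texture_rows.append(glcm_statistics(patch))
        shape_rows.append(contour_fourier_descriptor(region_contour(prop.image)))
    texture = DescriptorSet(np.array(texture_rows).reshape(-1, 6), "texture")
    shape = DescriptorSet(np.array(shape_rows).reshape(-1, N_SHAPE_COEFFS), "shape")
    return texture, shape
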