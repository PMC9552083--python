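"""Gland-cavity (lumen) detection and cavity-restricted HOG descriptors.

Lumens are the near-white open spaces enclosed by tissue.  Benign glands show
few large lumens whose boundaries fold into papillary protrusions; malignant
tissue shows many small smooth ones, so both the cavity geometry and the
gradient structure around cavity boundaries are discriminative.

The descriptor is a histogram of oriented gradients computed over 8x8-pixel
cells whose centers fall inside a cavity (or its 4-px boundary band), with 30
unsigned-orientation bins of 6 degrees and -- deliberately -- *no* block
normalization: stain intensity differences are informative in histology, unlike
the illumination differences HOG normalization was designed to cancel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.filters import threshold_multiotsu
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, remove_small_objects
from skimage.segmentation import clear_border

from .datatypes import DescriptorSet, LabeledImage, RegionLabelMap

N_ORIENTATIONS = 30
CELL_SIZE = 8  # px
MIN_CAVITY_AREA = 64  # px
BOUNDARY_BAND = 4  # px dilation capturing the papillary boundary


def _as_pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, LabeledImage) else np.asarray(image)


def segment_cavities(image) -> RegionLabelMap:
    """Detect bright lumen regions enclosed by tissue.

    The grayscale image is split into three intensity classes by multi-Otsu
    (nuclei / stroma / lumen); the brightest class, cleared of border-touching
    components (open background is not a cavity), hole-filled and filtered to
    area >= 64 px, gives the cavity label map.  A tissue-free (uniform) image
    yields zero cavities.
    """
    pixels = _as_pixels(image)
    gray = rgb2gray(pixels)
    if gray.std() < 1e-3:
        return RegionLabelMap(np.zeros(gray.shape, dtype=np.int32))
    try:
        thresholds = threshold_multiotsu(gray, classes=3)
    except ValueError:
        return RegionLabelMap(np.zeros(gray.shape, dtype=np.int32))
    bright = gray > thresholds[1]
    bright = clear_border(bright)  # enclosed-by-tissue rule
    bright = ndi.binary_fill_holes(bright)
    bright = remove_small_objects(bright, max_size=MIN_CAVITY_AREA - 1)
    labels, n = cc_label(bright, return_num=True)
    return RegionLabelMap(labels.astype(np.int32))


def pixel_gradients(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient (magnitude, orientation-bin) for HOG.

    Central differences per RGB channel; each pixel keeps the channel of
    maximal gradient magnitude.  Orientations are unsigned over [0, 180) and
    hard-assigned to one of 30 bins of 6 degrees.
    """
    img = np.asarray(pixels, dtype=float)
    if img.ndim == 2:
        img = img[..., None]
    gy = np.gradient(img, axis=0)
    gx = np.gradient(img, axis=1)
    mag = np.hypot(gx, gy)
    best = mag.argmax(axis=2)
    take = lambda g: np.take_along_axis(g, best[..., None], axis=2)[..., 0]
    gx_b, gy_b, mag_b = take(gx), take(gy), take(mag)
    theta = np.degrees(np.arctan2(gy_b, gx_b)) % 180.0
    bins = np.minimum((theta / (180.0 / N_ORIENTATIONS)).astype(int), N_ORIENTATIONS - 1)
    return mag_b, bins


def hog_cell_histograms(pixels, cell_mask: np.ndarray | None = None):
    """Unnormalized 30-bin orientation histograms over the 8x8 cell grid.

    Returns ``(histograms, cell_index)`` where ``histograms`` is (k, 30) and
    ``cell_index`` the (row, col) grid position of each retained cell.  With
    ``cell_mask`` given (a boolean pixel mask), only cells with >= 50% of their
    pixels inside the mask are kept; otherwise every full cell is returned.
    Histogram entries are summed gradient magnitudes -- no normalization.
    """
    pixels = _as_pixels(pixels)
    mag, bins = pixel_gradients(pixels)
    h, w = mag.shape
    nrows, ncols = h // CELL_SIZE, w // CELL_SIZE
    hists, where = [], []
    for r in range(nrows):
        for c in range(ncols):
            sl = np.s_[r * CELL_SIZE:(r + 1) * CELL_SIZE,
                       c * CELL_SIZE:(c + 1) * CELL_SIZE]
            if cell_mask is not None and cell_mask[sl].mean() < 0.5:
                continue
            hist = np.bincount(bins[sl].ravel(), weights=mag[sl].ravel(),
                               minlength=N_ORIENTATIONS)
            hists.append(hist)
            where.append((r, c))
    hists = np.array(hists).reshape(-1, N_ORIENTATIONS)
    return hists, np.array(where).reshape(-1, 2)


def cavity_hog_descriptors(image, cavities: RegionLabelMap) -> DescriptorSet:
    """One 30-bin unnormalized HOG per 8x8 cell lying within a cavity band.

    A cell belongs to a cavity when at least half of its pixels fall inside
    the cavity mask dilated by 4 px, which keeps the boundary cells where the
    papillary protrusions live.  No cavities -> an empty descriptor set.
    """
    pixels = _as_pixels(image)
    if cavities.n_regions == 0:
        return DescriptorSet(np.empty((0, N_ORIENTATIONS)), "cavity")
    band = dilation(cavities.labels > 0, disk(BOUNDARY_BAND))
    hists, _ = hog_cell_histograms(pixels, cell_mask=band)
    return DescriptorSet(hists, "cavity")
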