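"""Local keypoint descriptors and the color auto-correlogram.

SIFT (128-dim), SURF (64-dim) and ORB (32-byte binary) keypoint descriptors
feed the bag-of-visual-words encoder as generic local-appearance evidence.
This build extracts SIFT and ORB with scikit-image; no SURF implementation is
available, so requesting SURF raises a :class:`CapabilityError` unless
``allow_surf_fallback`` is set, in which case a 64-dim descriptor is produced
by pooling adjacent orientation-bin pairs of the SIFT descriptor (an upright,
half-width SIFT variant) -- the substitution is recorded on the returned set.

The color feature is the auto-correlogram: for each of 10 quantized colors c
and chessboard distance d in {1, 3, 5, 7, 9}, the probability that a pixel at
L-inf distance exactly d from a color-c pixel also has color c.  Because it
conditions on same-color co-occurrence rather than raw abundance it is far
less sensitive to global stain shifts than a plain color histogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import ORB, SIFT
from sklearn.cluster import KMeans

from .datatypes import CapabilityError, DescriptorSet, LabeledImage

LOCAL_METHODS = ("sift", "surf", "orb")
N_COLORS = 10
DISTANCES = (1, 3, 5, 7, 9)


def _as_pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, LabeledImage) else np.asarray(image)


def _gray_float(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 3:
        return rgb2gray(pixels)
    return pixels.astype(float) / 255.0 if pixels.dtype == np.uint8 else pixels


def _sift_descriptors(gray: np.ndarray) -> np.ndarray:
    det = SIFT()
    try:
        det.detect_and_extract(gray)
    except RuntimeError:  # no keypoints (e.g. uniform image)
        return np.empty((0, 128))
    return det.descriptors.astype(float)


def extract_local_descriptors(image, method: str,
                              allow_surf_fallback: bool = False) -> DescriptorSet:
    """Keypoint descriptors of the requested method (sift / surf / orb).

    A uniform image has no interest points and yields an empty set.  ORB's
    256-bit binary descriptors are packed into their canonical 32 bytes.
    """
    if method not in LOCAL_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {LOCAL_METHODS}")
    gray = _gray_float(_as_pixels(image))
    if method == "sift":
        return DescriptorSet(_sift_descriptors(gray), "sift")
    if method == "orb":
        det = ORB(n_keypoints=500)
        try:
            det.detect_and_extract(gray)
        except (RuntimeError, ValueError):
            return DescriptorSet(np.empty((0, 32)), "orb")
        packed = np.packbits(det.descriptors.astype(np.uint8), axis=1)
        return DescriptorSet(packed.astype(float), "orb")
    # SURF: not available in this build
    if not allow_surf_fallback:
        raise CapabilityError(
            "SURF is not available in this build; pass allow_surf_fallback=True "
            "(CLI: --allow-surf-fallback) to use 64-dim pooled upright-SIFT "
            "descriptors instead")
    return DescriptorSet(surf_fallback_from_sift(_sift_descriptors(gray)), "surf")


def surf_fallback_from_sift(sift_desc: np.ndarray) -> np.ndarray:
    """64-dim stand-in for SURF: SIFT's 4x4 grid with 8 orientation bins
    pooled pairwise down to 4 bins per spatial cell."""
    if len(sift_desc) == 0:
        return np.empty((0, 64))
    return sift_desc.reshape(-1, 16, 4, 2).sum(axis=3).reshape(-1, 64)


@dataclass
class ColorPalette:
    """Frozen 10-color RGB palette fitted on training images only.

    K-means in RGB space; quantization assigns every pixel to its nearest
    centroid, keeping the color vocabulary comparable across images.
    """

    centroids: np.ndarray  # (n_colors, 3) float in [0, 255]
    fit_ids: tuple = ()

    @classmethod
    def fit(cls, images, n_colors: int = N_COLORS, seed: int = 0,
            sample_per_image: int = 4000) -> "ColorPalette":
        rng = np.random.default_rng(seed)
        samples, ids = [], []
        for img in images:
            px = _as_pixels(img).reshape(-1, 3).astype(float)
            take = rng.choice(len(px), size=min(sample_per_image, len(px)),
                              replace=False)
            samples.append(px[take])
            ids.append(getattr(img, "id", None))
        pool = np.concatenate(samples)
        km = KMeans(n_clusters=n_colors, n_init=10, random_state=seed).fit(pool)
        # canonical order: darkest to brightest (stable across refits)
        luminance = km.cluster_centers_ @ np.array([0.299, 0.587, 0.114])
        centroids = km.cluster_centers_[np.argsort(luminance)]
        return cls(centroids=centroids, fit_ids=tuple(ids))

    @property
    def n_colors(self) -> int:
        return len(self.centroids)

    def quantize(self, pixels: np.ndarray) -> np.ndarray:
        px = _as_pixels(pixels).astype(float)
        flat = px.reshape(-1, 3)
        d2 = ((flat[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        return d2.argmin(axis=1).reshape(px.shape[:2])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"centroids": self.centroids.tolist(), "fit_ids": list(self.fit_ids)}))

    @classmethod
    def from_json(cls, path) -> "ColorPalette":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["centroids"], dtype=float), tuple(d["fit_ids"]))


def uniform_quantize(pixels: np.ndarray, n_colors: int = N_COLORS) -> np.ndarray:
    """Palette-free fallback quantization: equal luminance bands."""
    gray = _gray_float(_as_pixels(pixels))
    return np.minimum((gray * n_colors).astype(int), n_colors - 1)


def autocorrelogram_from_labels(labels: np.ndarray, n_colors: int,
                                distances=DISTANCES) -> np.ndarray:
    """Core auto-correlogram on an already color-quantized label image.

    Entry (c, d) = P(neighbor has color c | pixel has color c, L-inf distance
    exactly d), counting only in-bounds neighbors.  Colors absent from the
    image get 0.  Flattened color-major: index = c * len(distances) + d_index.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    if max(distances) >= min(h, w):
        raise ValueError("image smaller than the largest correlogram distance + 1")
    same = np.zeros((n_colors, len(distances)))
    total = np.zeros((n_colors, len(distances)))
    for di, d in enumerate(distances):
        offsets = [(dy, dx) for dy in range(-d, d + 1) for dx in range(-d, d + 1)
                   if max(abs(dy), abs(dx)) == d]
        for dy, dx in offsets:
            y0, y1 = max(0, -dy), min(h, h - dy)
            x0, x1 = max(0, -dx), min(w, w - dx)
            if y0 >= y1 or x0 >= x1:
                continue
            a = labels[y0:y1, x0:x1]
            b = labels[y0 + dy:y1 + dy, x0 + dx:x1 + dx]
            eq = (a == b)
            same[:, di] += np.bincount(a.ravel(), weights=eq.ravel(),
                                       minlength=n_colors)
            total[:, di] += np.bincount(a.ravel(), minlength=n_colors)
    with np.errstate(invalid="ignore"):
        out = np.where(total > 0, same / np.maximum(total, 1), 0.0)
    return out.ravel()


def color_autocorrelogram(image, palette: ColorPalette | None = None,
                          n_colors: int = N_COLORS,
                          distances=DISTANCES) -> np.ndarray:
    """50-dim color auto-correlogram of an RGB image.

    With a fitted :class:`ColorPalette` (the pipeline default) pixels are
    quantized against the frozen training palette; without one, equal
    luminance bands are used.
    """
    if n_colors < 2:
        raise ValueError("n_colors must be >= 2")
    dist = tuple(distances)
    if any(d <= 0 for d in dist) or list(dist) != sorted(set(dist)):
        raise ValueError("distances must be positive and strictly increasing")
    pixels = _as_pixels(image)
    if palette is not None:
        labels = palette.quantize(pixels)
        n_colors = palette.n_colors
    else:
        labels = uniform_quantize(pixels, n_colors)
    return autocorrelogram_from_labels(labels, n_colors, dist)
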