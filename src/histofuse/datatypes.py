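"""Shared containers used by every stage of the pipeline.

The unit of work is a :class:`LabeledImage` (one H&E-like RGB field of view with a
benign/malignant label).  Each feature extractor turns an image into a
:class:`DescriptorSet` -- a variable-row matrix whose width is fixed per feature
kind -- which the bag-of-visual-words encoder later collapses into a fixed
50-dimensional vector per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BENIGN = "benign"
MALIGNANT = "malignant"
CLASS_LABELS = (BENIGN, MALIGNANT)

#: fixed descriptor width per feature kind
DESCRIPTOR_WIDTHS = {
    "texture": 6,
    "shape": 60,
    "cavity": 30,
    "sift": 128,
    "surf": 64,
    "orb": 32,
}

#: the seven hand-crafted feature channels, in canonical order
HANDCRAFTED_CHANNELS = ("texture", "shape", "cavity", "sift", "surf", "orb", "color")

#: all eight branches of the fusion model
ALL_CHANNELS = HANDCRAFTED_CHANNELS + ("image",)


class CapabilityError(RuntimeError):
    """A requested capability is not available in this build."""


@dataclass
class LabeledImage:
    """An RGB pathology-like image with a binary diagnosis label."""

    pixels: np.ndarray  # (H, W, 3) uint8
    label: str
    id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}, got {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class DescriptorSet:
    """Variable-count matrix of local descriptors (rows = keypoints/nuclei/cells)."""

    values: np.ndarray  # (n, d) float
    kind: str

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.kind in DESCRIPTOR_WIDTHS:
            d = DESCRIPTOR_WIDTHS[self.kind]
            if v.size == 0:
                v = np.empty((0, d), dtype=float)
            if v.shape[1] != d:
                raise ValueError(
                    f"{self.kind} descriptors must have width {d}, got {v.shape[1]}"
                )
        if not np.all(np.isfinite(v)):
            raise ValueError("descriptors must be finite")
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        cols = [f"{self.kind}_{i}" for i in range(self.width)]
        pd.DataFrame(self.values, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str) -> "DescriptorSet":
        return cls(pd.read_csv(path).to_numpy(dtype=float), kind)


@dataclass
class RegionLabelMap:
    """Integer grid, 0 = background, 1..n = region ids (consecutive, disjoint)."""

    labels: np.ndarray  # (H, W) int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ValueError("region labels must be consecutive positive integers")

    @property
    def n_regions(self) -> int:
        return int(self.labels.max(initial=0))

    def mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    def to_png(self, path) -> None:
        """Write the label map as a 16-bit grayscale PNG."""
        import imageio.v3 as iio

        iio.imwrite(path, self.labels.astype(np.uint16))

    @classmethod
    def from_png(cls, path) -> "RegionLabelMap":
        import imageio.v3 as iio

        return cls(iio.imread(path).astype(np.int32))


@dataclass
class GroundTruth:
    """Generator-side truth: every placed nucleus and lumen, for oracle tests."""

    nucleus_centers: np.ndarray  # (n, 2) float, (row, col)
    nucleus_radii: np.ndarray  # (n,) float, pixels
    lumen_masks: np.ndarray  # (k, H, W) bool
    label: str

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_radii)

    @property
    def n_lumens(self) -> int:
        return self.lumen_masks.shape[0]

    def lumen_areas(self) -> np.ndarray:
        return self.lumen_masks.reshape(self.n_lumens, -1).sum(axis=1).astype(float)

    def nucleus_areas(self) -> np.ndarray:
        return np.pi * np.asarray(self.nucleus_radii, dtype=float) ** 2


@dataclass
class DatasetManifest:
    """Rows of (id, path, label, seed) describing a generated dataset on disk."""

    rows: list = field(default_factory=list)  # dicts: id, path, label, seed

    def __len__(self) -> int:
        return len(self.rows)

    def class_counts(self) -> dict:
        counts = {c: 0 for c in CLASS_LABELS}
        for r in self.rows:
            counts[r["label"]] += 1
        return counts

    @property
    def ids(self) -> list:
        return [r["id"] for r in self.rows]

    def labels_by_id(self) -> dict:
        return {r["id"]: r["label"] for r in self.rows}
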