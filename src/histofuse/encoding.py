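"""Bag-of-visual-words encoding and feature-space augmentation.

Each feature channel produces a variable number of local descriptors per
image.  A K-means codebook (K = 50) fitted on *training* descriptors turns
them into codeword counts per image, which TF-IDF weighting converts into the
fixed 50-dim vectors the fusion networks consume:

    tf(w)  = count(w) / total descriptors in the image
    idf(w) = ln((1 + N_train) / (1 + df(w))) + 1        (smoothed)
    weight = tf * idf

Two feature-space augmentation schemes generate perturbed copies of training
vectors.  Method 1 (for codeword-count features) adds elementwise
ceil(N(0, 1)) integer noise, clamped at zero so counts stay counts.  Method 2
(for the color feature) adds N(0, 1) noise and squashes through
f(x) = |1 / (1 + e^-x)| - 0.5, mapping copies into (-0.5, 0.5) with f(0) = 0;
originals are kept untransformed in both schemes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin

from .datatypes import DescriptorSet

K_CODEWORDS = 50


@dataclass
class Codebook:
    """K-means centroids + per-codeword document frequencies (training only)."""

    centroids: np.ndarray  # (K, d)
    doc_freq: np.ndarray  # (K,) number of training images containing the word
    n_train: int
    kind: str = ""
    seed: int = 0
    fit_ids: tuple = ()  # image ids the codebook was fitted on (leakage guard)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.doc_freq = np.asarray(self.doc_freq, dtype=float)
        if len(self.doc_freq) != len(self.centroids):
            raise ValueError("doc_freq length must equal the number of centroids")
        if (self.doc_freq < 0).any() or (self.doc_freq > self.n_train).any():
            raise ValueError("document frequencies must lie in [0, n_train]")

    @property
    def K(self) -> int:
        return len(self.centroids)

    @property
    def width(self) -> int:
        return self.centroids.shape[1]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "centroids": self.centroids.tolist(),
            "doc_freq": self.doc_freq.tolist(),
            "n_train": self.n_train, "kind": self.kind, "seed": self.seed,
            "fit_ids": list(self.fit_ids),
        }))

    @classmethod
    def from_json(cls, path) -> "Codebook":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["centroids"]), np.asarray(d["doc_freq"]),
                   d["n_train"], d["kind"], d["seed"], tuple(d["fit_ids"]))


def _values(ds) -> np.ndarray:
    return ds.values if isinstance(ds, DescriptorSet) else np.atleast_2d(np.asarray(ds, float))


def build_codebook(training_descriptor_sets, K: int = K_CODEWORDS, seed: int = 0,
                   kind: str = "", fit_ids=()) -> Codebook:
    """Fit a K-word codebook on pooled training descriptors.

    Requires at least K unique pooled descriptors.  Document frequencies come
    from the hard assignments of each training image's descriptor set.
    """
    mats = [_values(ds) for ds in training_descriptor_sets]
    nonempty = [m for m in mats if m.size]
    if not nonempty:
        raise ValueError("no training descriptors")
    pooled = np.concatenate(nonempty)
    if len(pooled) < K or len(np.unique(pooled, axis=0)) < K:
        raise ValueError(f"need at least {K} unique descriptors, "
                         f"got {len(np.unique(pooled, axis=0))}")
    km = KMeans(n_clusters=K, n_init=10, tol=1e-4, random_state=seed).fit(pooled)
    doc_freq = np.zeros(K)
    for m in mats:
        if m.size:
            words = pairwise_distances_argmin(m, km.cluster_centers_)
            doc_freq[np.unique(words)] += 1
    return Codebook(km.cluster_centers_, doc_freq, n_train=len(mats),
                    kind=kind, seed=seed, fit_ids=tuple(fit_ids))


def encode_counts(descriptors, codebook: Codebook) -> np.ndarray:
    """Raw codeword counts of one image's descriptor set (length K)."""
    m = _values(descriptors)
    if m.size == 0:
        return np.zeros(codebook.K)
    if m.shape[1] != codebook.width:
        raise ValueError(f"descriptor width {m.shape[1]} != codebook width "
                         f"{codebook.width}")
    words = pairwise_distances_argmin(m, codebook.centroids)
    return np.bincount(words, minlength=codebook.K).astype(float)


def tfidf_from_counts(counts: np.ndarray, codebook: Codebook) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts)
    tf = counts / total
    idf = np.log((1.0 + codebook.n_train) / (1.0 + codebook.doc_freq)) + 1.0
    return tf * idf


def encode_tfidf(descriptors, codebook: Codebook) -> np.ndarray:
    """TF-IDF-weighted codeword histogram (length K, nonnegative).

    An empty descriptor set encodes to the zero vector -- blank regions occur
    in valid images and are not an error.
    """
    return tfidf_from_counts(encode_counts(descriptors, codebook), codebook)


@dataclass
class AugmentedFeatureSet:
    """Originals plus n perturbed copies of each, with provenance."""

    features: np.ndarray  # (m * (n + 1), K): m originals first, then copies
    is_original: np.ndarray  # (m * (n + 1),) bool
    origin_index: np.ndarray  # row index of the source original
    seed: int

    def __len__(self) -> int:
        return len(self.features)

    @property
    def originals(self) -> np.ndarray:
        return self.features[self.is_original]

    @property
    def copies(self) -> np.ndarray:
        return self.features[~self.is_original]


def _augment(feature_vectors, n_copies, seed, perturb) -> AugmentedFeatureSet:
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    X = np.atleast_2d(np.asarray(feature_vectors, dtype=float))
    m = len(X)
    rng = np.random.default_rng(seed)
    blocks, origin = [X.copy()], [np.arange(m)]
    for _ in range(n_copies):
        noise = rng.standard_normal(X.shape)
        blocks.append(perturb(X, noise))
        origin.append(np.arange(m))
    features = np.concatenate(blocks)
    is_original = np.zeros(len(features), dtype=bool)
    is_original[:m] = True
    return AugmentedFeatureSet(features, is_original, np.concatenate(origin), seed)


def augment_counts(feature_vectors, n_copies: int, seed: int = 0) -> AugmentedFeatureSet:
    """Augmentation Method 1, for nonnegative codeword-count vectors.

    Each copy is ``max(original + ceil(N(0,1)), 0)`` elementwise: integer
    perturbations of the counts, clamped at zero because counts are
    nonnegative.  Originals are retained bit-identically, so m vectors yield
    m * (n_copies + 1) rows.
    """
    X = np.atleast_2d(np.asarray(feature_vectors, dtype=float))
    if (X < 0).any():
        raise ValueError("count features must be nonnegative")
    return _augment(X, n_copies, seed,
                    lambda x, z: np.maximum(x + np.ceil(z), 0.0))


def augment_color(feature_vectors, n_copies: int, seed: int = 0) -> AugmentedFeatureSet:
    """Augmentation Method 2, for the color feature.

    Copies are ``f(original + N(0,1))`` with ``f(x) = |1/(1+e^-x)| - 0.5``,
    so every augmented component lies strictly in (-0.5, 0.5) and a zero
    pre-activation maps to exactly 0.  Originals stay untransformed (their
    scale intentionally differs from the copies').
    """
    def squash(x, z):
        t = x + z
        return np.abs(1.0 / (1.0 + np.exp(-t))) - 0.5

    return _augment(feature_vectors, n_copies, seed, squash)


def expected_ceil_standard_normal(span: int = 12) -> float:
    """E[ceil(Z)], Z ~ N(0,1), by numerical quadrature over integer cells."""
    from scipy.stats import norm

    ks = np.arange(-span, span + 1)
    return float(np.sum(ks * (norm.cdf(ks) - norm.cdf(ks - 1.0))))
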