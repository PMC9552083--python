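"""BoW codebook + TF-IDF encoding and the two feature-space augmentation
algorithms."""

import numpy as np
import pytest
from scipy.stats import norm

from histofuse.encoding import (AugmentedFeatureSet, Codebook, augment_color,
                                augment_counts, build_codebook, encode_counts,
                                encode_tfidf, expected_ceil_standard_normal,
                                tfidf_from_counts)


def _point_sets(rng, n_sets=5, per_set=30, width=4):
    return [rng.normal(0, 10, (per_set, width)) for _ in range(n_sets)]


def test_fifty_distinct_points_become_their_own_centroids():
    rng = np.random.default_rng(0)
    points = rng.normal(0, 10, (50, 3))
    cb = build_codebook([points], K=50, seed=0)
    got = set(map(tuple, np.round(cb.centroids, 6)))
    want = set(map(tuple, np.round(points, 6)))
    assert got == want


def test_too_few_unique_descriptors_raise():
    rng = np.random.default_rng(1)
    points = rng.normal(0, 1, (49, 3))
    with pytest.raises(ValueError, match="unique"):
        build_codebook([np.vstack([points, points])], K=50, seed=0)


def test_codebook_is_seed_deterministic():
    rng = np.random.default_rng(2)
    sets = _point_sets(rng)
    a = build_codebook(sets, K=50, seed=5)
    b = build_codebook(sets, K=50, seed=5)
    np.testing.assert_array_equal(a.centroids, b.centroids)
    np.testing.assert_array_equal(a.doc_freq, b.doc_freq)


def test_exact_assignment_counts():
    rng = np.random.default_rng(3)
    cb = build_codebook(_point_sets(rng, per_set=40), K=50, seed=0)
    j = 7
    descriptors = np.tile(cb.centroids[j], (5, 1))
    counts = encode_counts(descriptors, cb)
    assert counts[j] == 5
    assert counts.sum() == 5


def test_empty_descriptor_set_encodes_to_zero_vector():
    rng = np.random.default_rng(4)
    cb = build_codebook(_point_sets(rng), K=50, seed=0)
    vec = encode_tfidf(np.empty((0, 4)), cb)
    assert vec.shape == (50,)
    assert np.allclose(vec, 0.0)


def test_count_conservation_on_random_sets():
    rng = np.random.default_rng(5)
    cb = build_codebook(_point_sets(rng), K=50, seed=0)
    for _ in range(20):
        descriptors = rng.normal(0, 10, (rng.integers(1, 40), 4))
        assert encode_counts(descriptors, cb).sum() == len(descriptors)


def test_centroid_round_trip_is_identity_pattern():
    rng = np.random.default_rng(6)
    cb = build_codebook(_point_sets(rng), K=50, seed=0)
    counts = np.stack([encode_counts(c[None], cb) for c in cb.centroids])
    np.testing.assert_array_equal(counts, np.eye(50))


def test_tfidf_zero_exactly_where_counts_zero():
    rng = np.random.default_rng(7)
    cb = build_codebook(_point_sets(rng), K=50, seed=0)
    counts = rng.integers(0, 4, 50).astype(float)
    weights = tfidf_from_counts(counts, cb)
    assert (weights >= 0).all()
    np.testing.assert_array_equal(weights == 0, counts == 0)


def test_width_mismatch_raises():
    rng = np.random.default_rng(8)
    cb = build_codebook(_point_sets(rng, width=4), K=50, seed=0)
    with pytest.raises(ValueError, match="width"):
        encode_counts(rng.normal(0, 1, (3, 5)), cb)


def test_codebook_json_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    cb = build_codebook(_point_sets(rng), K=50, seed=0, kind="texture",
                        fit_ids=("a", "b"))
    cb.to_json(tmp_path / "cb.json")
    loaded = Codebook.from_json(tmp_path / "cb.json")
    np.testing.assert_allclose(loaded.centroids, cb.centroids)
    assert loaded.fit_ids == ("a", "b")
    assert loaded.n_train == cb.n_train


# ------------------------------------------------------------- augmentation

def test_count_augmentation_row_algebra():
    rng = np.random.default_rng(10)
    X = rng.integers(0, 20, (4, 50)).astype(float)
    aug = augment_counts(X, n_copies=3, seed=1)
    assert len(aug) == 16  # 4 originals + 12 copies
    np.testing.assert_array_equal(aug.originals, X)
    diffs = aug.copies - np.tile(X, (3, 1))
    assert np.allclose(diffs, np.round(diffs))  # integer perturbations
    assert (aug.features >= 0).all()


def test_count_augmentation_is_seeded():
    X = np.arange(20, dtype=float).reshape(2, 10)
    a = augment_counts(X, 2, seed=3)
    b = augment_counts(X, 2, seed=3)
    np.testing.assert_array_equal(a.features, b.features)
    c = augment_counts(X, 2, seed=4)
    assert not np.array_equal(a.features, c.features)


def test_count_augmentation_rejects_bad_inputs():
    with pytest.raises(ValueError):
        augment_counts(np.ones((2, 3)), 0)
    with pytest.raises(ValueError):
        augment_counts(np.ones((2, 3)), -1)
    with pytest.raises(ValueError, match="nonnegative"):
        augment_counts(-np.ones((2, 3)), 1)


def test_count_copy_mean_matches_ceiling_noise_expectation():
    """Per-dimension mean of Algorithm-1 copies equals the original mean plus
    E[ceil(N(0,1))], within 3 standard errors over 1000+ copies (originals
    large enough that the nonnegativity clamp never fires)."""
    X = np.full((1, 50), 40.0)
    aug = augment_counts(X, n_copies=1200, seed=11)
    e_ceil = expected_ceil_standard_normal()
    assert e_ceil == pytest.approx(0.5, abs=1e-9)
    # sd of ceil(Z) via the same numerical oracle
    ks = np.arange(-12, 13)
    pk = norm.cdf(ks) - norm.cdf(ks - 1.0)
    sd = np.sqrt(np.sum(ks**2 * pk) - e_ceil**2)
    se = sd / np.sqrt(len(aug.copies))
    per_dim = aug.copies.mean(axis=0)
    assert np.all(np.abs(per_dim - (40.0 + e_ceil)) < 3 * se + 1e-12)


def test_color_augmentation_range_and_retention():
    rng = np.random.default_rng(12)
    X = rng.uniform(0, 1, (2, 50))
    aug = augment_color(X, n_copies=5, seed=2)
    assert len(aug) == 12
    np.testing.assert_array_equal(aug.features[:2], X)
    copies = aug.copies
    assert (copies > -0.5).all() and (copies < 0.5).all()


def test_color_squash_maps_zero_preactivation_to_zero():
    # reconstruct the noise stream, then feed originals = -noise so that the
    # pre-activation is exactly zero -> f(0) must be exactly 0
    rng = np.random.default_rng(77)
    noise = rng.standard_normal((3, 50))
    aug = augment_color(-noise, n_copies=1, seed=77)
    np.testing.assert_array_equal(aug.copies, np.zeros((3, 50)))


def test_provenance_flags():
    X = np.ones((3, 5))
    aug = augment_counts(X, 2, seed=0)
    assert aug.is_original.sum() == 3
    assert list(aug.origin_index[:3]) == [0, 1, 2]
    assert list(aug.origin_index[3:6]) == [0, 1, 2]
    assert isinstance(aug, AugmentedFeatureSet)
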