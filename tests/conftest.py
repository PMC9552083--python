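"""Shared fixtures.

The expensive session fixtures (extracted feature store, end-to-end benchmark)
are computed once and shared between the unit suite and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import histofuse as hf
from histofuse.datatypes import DatasetManifest
from histofuse.pipeline import FeatureStore, run_experiment, split_dataset
from histofuse.synthetic_data import generate_dataset

BENCH_SEED = 0
BENCH_N_PER_CLASS = 100
BENCH_SIDE = 224
BENCH_EPOCHS = 15
BENCH_BATCH = 16


@pytest.fixture(scope="session")
def gen224() -> hf.GenParams:
    return hf.GenParams.for_size(224)


@pytest.fixture(scope="session")
def benign_image(gen224):
    return hf.generate_image("benign", gen224, seed=1)


@pytest.fixture(scope="session")
def malignant_image(gen224):
    return hf.generate_image("malignant", gen224, seed=1)


@pytest.fixture(scope="session")
def small_store(gen224):
    """12 extracted images (6 per class) for encoder/pipeline tests."""
    manifest = generate_dataset(6, 6, gen224, seed=3)
    store = FeatureStore.from_manifest(manifest)
    store.extract()
    return store


@pytest.fixture(scope="session")
def small_splits(small_store):
    manifest = DatasetManifest(rows=[{"id": i, "label": img.label}
                                     for i, img in sorted(small_store.images.items())])
    return split_dataset(manifest, seed=3)


@pytest.fixture(scope="session")
def benchmark_bundle():
    """The seeded end-to-end synthetic benchmark: 200 images, 3:1:1 split,
    ResNet-18 backbone, 15 epochs, batch 16, all comparison arms."""
    return run_experiment({
        "backbone": "resnet18",
        "seed": BENCH_SEED,
        "epochs": BENCH_EPOCHS,
        "batch_size": BENCH_BATCH,
        "dataset": {"n_per_class": BENCH_N_PER_CLASS, "image_size": BENCH_SIDE},
    })
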