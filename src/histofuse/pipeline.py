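"""End-to-end orchestration: extract -> encode -> train -> evaluate.

The pipeline enforces a strict no-leakage discipline: the bag-of-visual-words
codebooks, the color palette and any feature-space augmentation are fitted on
training images only, and :class:`LeakageError` is raised if an encoder was
fitted on ids outside the training split.

Training recipe: SGD with momentum 0.9, weight decay 0.001, initial learning
rate 0.01 decayed by 0.1 every 7 epochs, cross-entropy on the final 2-class
output, batch size 16.  The matching + integrated trunk is randomly
initialized, its BatchNorm statistics are calibrated on the training split,
and the fully connected fusion heads are trained on the frozen 128-dim
embeddings (an MLP-probe protocol that keeps every experiment arm comparable
at desk scale); the architecture itself is differentiable end to end.  The
best-validation-accuracy checkpoint (ties -> earlier epoch) is evaluated.
Malignant is the positive class throughout: sensitivity is the
malignant-class recall, specificity the benign-class recall, and the AUC is
the trapezoidal area under the ROC of the malignant-class probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import nn
from .appearance_features import ColorPalette, color_autocorrelogram, \
    extract_local_descriptors
from .cavity_features import cavity_hog_descriptors, segment_cavities
from .datatypes import CLASS_LABELS, HANDCRAFTED_CHANNELS, BENIGN, MALIGNANT, \
    DatasetManifest, LabeledImage
from .encoding import augment_color, augment_counts, build_codebook, \
    encode_counts, tfidf_from_counts
from .networks import FusionModel, FusionModelSpec, build_fusion_model
from .nucleus_features import nucleus_descriptors, segment_nuclei
from .synthetic_data import GenParams, generate_dataset, load_image

COUNT_CHANNELS = ("texture", "shape", "cavity", "sift", "surf", "orb")


class LeakageError(RuntimeError):
    """An encoder was fitted on images outside the training split."""


# --------------------------------------------------------------------- splits

@dataclass
class Splits:
    train: tuple
    val: tuple
    test: tuple
    ratios: tuple = (3, 1, 1)
    seed: int = 0

    def all_ids(self) -> tuple:
        return self.train + self.val + self.test


def split_dataset(manifest: DatasetManifest, ratios=(3, 1, 1),
                  seed: int = 0) -> Splits:
    """Stratified train/validation/test split at the given ratio.

    Per class, floor(n * r / sum(r)) images go to validation and test; the
    remainder stays in training.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    parts = sum(ratios)
    rng = np.random.default_rng(seed)
    by_class = {c: [r["id"] for r in manifest.rows if r["label"] == c]
                for c in CLASS_LABELS}
    train, val, test = [], [], []
    for c, ids in by_class.items():
        if not ids:
            continue
        if len(ids) < parts:
            raise ValueError(f"class {c!r} has {len(ids)} images, fewer than "
                             f"the {parts} split parts")
        ids = list(ids)
        rng.shuffle(ids)
        n_val = len(ids) * ratios[1] // parts
        n_test = len(ids) * ratios[2] // parts
        val += ids[:n_val]
        test += ids[n_val:n_val + n_test]
        train += ids[n_val + n_test:]
    return Splits(tuple(sorted(train)), tuple(sorted(val)), tuple(sorted(test)),
                  tuple(ratios), seed)


def _stratified_two_way(ids, labels, val_fraction: float, seed: int):
    """Inner train/val split used by cross-validation folds."""
    rng = np.random.default_rng(seed)
    train, val = [], []
    for c in CLASS_LABELS:
        members = [i for i in ids if labels[i] == c]
        rng.shuffle(members)
        n_val = max(1, int(len(members) * val_fraction)) if members else 0
        val += members[:n_val]
        train += members[n_val:]
    return tuple(sorted(train)), tuple(sorted(val))


# -------------------------------------------------------------- feature store

@dataclass
class FeatureStore:
    """Images plus their raw (pre-encoding) descriptor sets, keyed by id."""

    images: dict = field(default_factory=dict)  # id -> LabeledImage
    raw: dict = field(default_factory=dict)  # id -> {channel: DescriptorSet}

    @classmethod
    def from_manifest(cls, manifest: DatasetManifest) -> "FeatureStore":
        store = cls()
        for row in manifest.rows:
            store.images[row["id"]] = load_image(row)
        return store

    @property
    def labels(self) -> dict:
        return {i: img.label for i, img in self.images.items()}

    def extract(self, ids=None, allow_surf_fallback: bool = True) -> None:
        """Compute the six descriptor-set channels for every image.

        SURF descriptors come from the pooled-SIFT fallback (this build has no
        SURF); pass ``allow_surf_fallback=False`` to get the capability error
        instead.
        """
        for image_id in (ids if ids is not None else sorted(self.images)):
            if image_id in self.raw:
                continue
            img = self.images[image_id]
            regions = segment_nuclei(img)
            texture, shape = nucleus_descriptors(img, regions)
            cavities = segment_cavities(img)
            cavity = cavity_hog_descriptors(img, cavities)
            sift = extract_local_descriptors(img, "sift")
            surf = extract_local_descriptors(img, "surf",
                                             allow_surf_fallback=allow_surf_fallback)
            orb = extract_local_descriptors(img, "orb")
            self.raw[image_id] = {"texture": texture, "shape": shape,
                                  "cavity": cavity, "sift": sift,
                                  "surf": surf, "orb": orb}


@dataclass
class Encoders:
    """Frozen training-fitted encoders: one codebook per descriptor channel
    plus the color palette."""

    codebooks: dict  # channel -> Codebook
    palette: ColorPalette
    fit_ids: tuple

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for ch, cb in self.codebooks.items():
            cb.to_json(out / f"codebook_{ch}.json")
        self.palette.to_json(out / "palette.json")


def fit_encoders(store: FeatureStore, train_ids, K: int = 50,
                 seed: int = 0) -> Encoders:
    """Fit all codebooks + the color palette on the given (training) ids."""
    train_ids = tuple(train_ids)
    codebooks = {}
    for ch in COUNT_CHANNELS:
        sets = [store.raw[i][ch] for i in train_ids]
        codebooks[ch] = build_codebook(sets, K=K, seed=seed, kind=ch,
                                       fit_ids=train_ids)
    palette = ColorPalette.fit([store.images[i] for i in train_ids], seed=seed)
    return Encoders(codebooks, palette, train_ids)


def assert_no_leakage(encoders: Encoders, splits: Splits) -> None:
    """Raise LeakageError if any encoder saw validation/test images."""
    train = set(splits.train)
    for ch, cb in encoders.codebooks.items():
        extra = set(cb.fit_ids) - train
        if extra:
            raise LeakageError(
                f"codebook for {ch!r} was fitted on non-training ids: "
                f"{sorted(extra)[:5]}")
    extra = set(i for i in encoders.palette.fit_ids if i is not None) - train
    if extra:
        raise LeakageError(f"color palette was fitted on non-training ids: "
                           f"{sorted(extra)[:5]}")


@dataclass
class EncodedDataset:
    """Per-image 7-channel 50-dim encoded features, plus provenance."""

    features: dict  # id -> {channel: (50,) array}
    labels: dict  # id -> label
    images: dict  # id -> LabeledImage (DL branch input)
    encoders: Encoders

    def matrix(self, ids, channel: str) -> np.ndarray:
        return np.stack([self.features[i][channel] for i in ids])

    def y(self, ids) -> np.ndarray:
        return np.array([self.labels[i] == MALIGNANT for i in ids], dtype=int)

    def to_csv(self, path, ids=None) -> None:
        ids = list(ids) if ids is not None else sorted(self.features)
        cols = [f"{ch}_{k}" for ch in HANDCRAFTED_CHANNELS for k in range(50)]
        data = [np.concatenate([self.features[i][ch]
                                for ch in HANDCRAFTED_CHANNELS]) for i in ids]
        df = pd.DataFrame(data, index=ids, columns=cols)
        df.insert(0, "label", [self.labels[i] for i in ids])
        df.to_csv(path)


def encode_dataset(store: FeatureStore, encoders: Encoders) -> EncodedDataset:
    """TF-IDF-encode every image's descriptor sets + its color correlogram."""
    features = {}
    for image_id, raw in store.raw.items():
        vecs = {}
        for ch in COUNT_CHANNELS:
            cb = encoders.codebooks[ch]
            vecs[ch] = tfidf_from_counts(encode_counts(raw[ch], cb), cb)
        vecs["color"] = color_autocorrelogram(store.images[image_id],
                                              palette=encoders.palette)
        features[image_id] = vecs
    return EncodedDataset(features, dict(store.labels), dict(store.images),
                          encoders)


def augment_training_features(store: FeatureStore, dataset: EncodedDataset,
                              train_ids, n_copies: int, seed: int = 0):
    """Feature-space augmentation of the *training* rows only.

    Count channels go through Method 1 (on the raw codeword counts, before
    TF-IDF); the color channel through Method 2.  Returns
    ``(aug_features, aug_labels, aug_origins)``: per-channel feature dicts,
    labels, and source-image ids of the synthetic rows (originals are the
    training rows themselves and are not duplicated here).
    """
    train_ids = list(train_ids)
    enc = dataset.encoders
    rng = np.random.default_rng(seed)
    counts = {ch: np.stack([encode_counts(store.raw[i][ch], enc.codebooks[ch])
                            for i in train_ids]) for ch in COUNT_CHANNELS}
    color = np.stack([dataset.features[i]["color"] for i in train_ids])
    per_channel_copies = {}
    for ch in COUNT_CHANNELS:
        aug = augment_counts(counts[ch], n_copies, seed=int(rng.integers(2**31)))
        per_channel_copies[ch] = np.stack([
            tfidf_from_counts(c, enc.codebooks[ch]) for c in aug.copies])
    aug_color = augment_color(color, n_copies, seed=int(rng.integers(2**31)))
    per_channel_copies["color"] = aug_color.copies
    aug_features, aug_labels, aug_origins = [], [], []
    for row in range(n_copies * len(train_ids)):
        origin = train_ids[row % len(train_ids)]
        aug_features.append({ch: per_channel_copies[ch][row]
                             for ch in HANDCRAFTED_CHANNELS})
        aug_labels.append(dataset.labels[origin])
        aug_origins.append(origin)
    return aug_features, aug_labels, aug_origins


# ------------------------------------------------------------------- metrics

@dataclass
class EvalReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None
    confusion: np.ndarray  # [[tn, fp], [fn, tp]]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    predictions: pd.DataFrame  # id, label, p_malignant, predicted

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc,
                "confusion": self.confusion.tolist()}


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Sensitivity / specificity / accuracy from a 2x2 table (malignant = positive)."""
    total = tp + fn + tn + fp
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / total if total else float("nan"),
    }


def evaluate_predictions(y_true: np.ndarray, p_malignant: np.ndarray,
                         ids=None, threshold: float = 0.5) -> EvalReport:
    """Full evaluation report from malignant-class probabilities."""
    y_true = np.asarray(y_true, dtype=int)
    p = np.asarray(p_malignant, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    m = metrics_from_confusion(tp, fn, tn, fp)
    if len(np.unique(y_true)) < 2:
        auc_value, fpr, tpr = None, np.array([]), np.array([])
    else:
        fpr, tpr, _ = roc_curve(y_true, p)
        auc_value = float(_trapezoid_auc(fpr, tpr))
    frame = pd.DataFrame({
        "id": ids if ids is not None else np.arange(len(y_true)),
        "label": np.where(y_true == 1, MALIGNANT, BENIGN),
        "p_malignant": p, "predicted": np.where(pred == 1, MALIGNANT, BENIGN)})
    return EvalReport(accuracy=m["accuracy"], sensitivity=m["sensitivity"],
                      specificity=m["specificity"], auc=auc_value,
                      confusion=np.array([[tn, fp], [fn, tp]]),
                      roc_fpr=fpr, roc_tpr=tpr, predictions=frame)


# ------------------------------------------------------------------ training

@dataclass
class Hyperparams:
    """The SGD training recipe."""

    momentum: float = 0.9
    weight_decay: float = 0.001
    lr0: float = 0.01
    lr_decay: float = 0.1
    lr_step_epochs: int = 7
    epochs: int = 15
    batch_size: int = 16
    seed: int = 0
    auxiliary_loss: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.lr0 <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def learning_rate(self, epoch: int) -> float:
        """Stepwise-decayed learning rate for a 1-indexed epoch."""
        return self.lr0 * self.lr_decay ** ((epoch - 1) // self.lr_step_epochs)


@dataclass
class History:
    epochs: list = field(default_factory=list)  # dicts per epoch

    def __len__(self) -> int:
        return len(self.epochs)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


@dataclass
class TrainedModel:
    model: FusionModel
    embeddings: dict  # id -> {channel: (128,)}
    history: History
    best_epoch: int


def _spread(ids, n):
    """Evenly spaced subset (keeps both classes when ids are sorted by label)."""
    ids = list(ids)
    if len(ids) <= n:
        return ids
    idx = np.linspace(0, len(ids) - 1, n).astype(int)
    return [ids[i] for i in idx]


def compute_embeddings(model: FusionModel, dataset: EncodedDataset, ids,
                       calibration_ids=None, batch_size: int = 16,
                       extra_rows=()) -> dict:
    """Frozen-trunk 128-dim embeddings for every id and branch.

    BatchNorm running statistics are first calibrated on (a subset of) the
    training ids, then all embeddings are computed in inference mode.
    ``extra_rows`` carries ``(feature_dict, origin_id)`` pairs for augmented
    rows, which reuse their origin image's DL-branch embedding.
    """
    ids = list(ids)
    channels = model.branch_order

    def channel_batch(id_batch, name):
        if name == "image":
            return np.stack([np.asarray(dataset.images[i].pixels, dtype=np.float32)
                             / 255.0 for i in id_batch])
        return dataset.matrix(id_batch, name)

    with nn.no_grad():
        if calibration_ids:
            calib = _spread(calibration_ids, 2 * batch_size)
            nn.set_bn_calibration(model.integrated, True)
            for name in channels:
                if name != "image":
                    nn.set_bn_calibration(model.matching[name], True)
                for k in range(0, len(calib), batch_size):
                    model.embed_channel(name, channel_batch(
                        calib[k:k + batch_size], name), training=True)
                if name != "image":
                    nn.set_bn_calibration(model.matching[name], False)
            nn.set_bn_calibration(model.integrated, False)
        embeddings = {i: {} for i in ids}
        for name in channels:
            for k in range(0, len(ids), batch_size):
                id_batch = ids[k:k + batch_size]
                emb = model.embed_channel(name, channel_batch(id_batch, name))
                for i, row in zip(id_batch, emb):
                    embeddings[i][name] = row
        for j, (feats, origin) in enumerate(extra_rows):
            key = f"__aug_{j}"
            embeddings[key] = {}
            for name in channels:
                if name == "image":
                    embeddings[key][name] = embeddings[origin][name]
                    continue
                batch = np.stack([np.asarray(feats[name], dtype=np.float32)])
                embeddings[key][name] = model.embed_channel(name, batch)[0]
    return embeddings


def _stack_embeddings(embeddings: dict, ids, channels) -> dict:
    return {name: np.stack([embeddings[i][name] for i in ids])
            for name in channels}


def _head_state(model: FusionModel) -> list:
    return [p.value.copy() for p in model.head_parameters()]


def _load_head_state(model: FusionModel, state) -> None:
    for p, v in zip(model.head_parameters(), state, strict=True):
        p.value = v.copy()


def train_heads(model: FusionModel, embeddings: dict, labels: dict,
                splits: Splits, hyperparams: Hyperparams,
                extra_train_rows=()) -> tuple[History, int]:
    """SGD training of the fusion heads on frozen embeddings.

    Returns the history and the (1-indexed) best-validation epoch; the model
    is left holding the best checkpoint.  ``extra_train_rows`` are
    (embedding-key, label) pairs for augmented rows.
    """
    hp = hyperparams
    rng = np.random.default_rng(hp.seed)
    channels = model.branch_order
    aug_labels = dict(extra_train_rows)
    train_keys = list(splits.train) + list(aug_labels)
    y_of = lambda k: int((aug_labels[k] if k in aug_labels else labels[k])
                         == MALIGNANT)
    val_x = _stack_embeddings(embeddings, splits.val, channels)
    val_y = np.array([y_of(i) for i in splits.val])
    optimizer = nn.SGD(model.head_parameters(), lr=hp.lr0,
                       momentum=hp.momentum, weight_decay=hp.weight_decay)
    history = History()
    best = (-1.0, 0, None)  # (val_acc, epoch, state); ties keep earlier epoch
    for epoch in range(1, hp.epochs + 1):
        optimizer.lr = hp.learning_rate(epoch)
        order = list(train_keys)
        rng.shuffle(order)
        losses, hits, seen = [], 0, 0
        for k0 in range(0, len(order), hp.batch_size):
            keys = order[k0:k0 + hp.batch_size]
            xb = _stack_embeddings(embeddings, keys, channels)
            yb = np.array([y_of(k) for k in keys])
            logits, _, branch_probs = model.head_forward(xb, training=True)
            loss, dlogits = nn.cross_entropy(logits, yb)
            aux = None
            if hp.auxiliary_loss:
                aux = {}
                for name, probs in branch_probs.items():
                    d = probs.copy()
                    d[np.arange(len(yb)), yb] -= 1.0
                    aux[name] = d / (len(yb) * len(branch_probs))
            optimizer.zero_grad()
            model.head_backward(dlogits, extra_dlogits=aux)
            optimizer.step()
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == yb).sum())
            seen += len(yb)
        with nn.no_grad():
            val_logits, _, _ = model.head_forward(val_x, training=False)
        val_loss, _ = nn.cross_entropy(val_logits, val_y)
        val_acc = float((val_logits.argmax(axis=1) == val_y).mean())
        history.epochs.append({
            "epoch": epoch, "lr": optimizer.lr,
            "train_loss": float(np.mean(losses)), "train_acc": hits / seen,
            "val_loss": val_loss, "val_acc": val_acc})
        if val_acc > best[0]:
            best = (val_acc, epoch, _head_state(model))
    _load_head_state(model, best[2])
    return history, best[1]


def train_model(model: FusionModel, splits: Splits, hyperparams: Hyperparams,
                dataset: EncodedDataset) -> TrainedModel:
    """Full training entry point on an encoded dataset.

    Verifies the no-leakage contract, calibrates the trunk on the training
    split, embeds every image, and trains the fusion heads with
    best-validation checkpointing.
    """
    if not splits.train:
        raise ValueError("empty training split")
    assert_no_leakage(dataset.encoders, splits)
    embeddings = compute_embeddings(model, dataset, splits.all_ids(),
                                    calibration_ids=splits.train,
                                    batch_size=hyperparams.batch_size)
    history, best_epoch = train_heads(model, embeddings, dataset.labels,
                                      splits, hyperparams)
    return TrainedModel(model, embeddings, history, best_epoch)


def evaluate_model(trained: TrainedModel, test_ids, dataset: EncodedDataset) -> EvalReport:
    """Evaluate a trained model on the test ids (accuracy/sens/spec/AUC)."""
    test_ids = list(test_ids)
    if not test_ids:
        raise ValueError("empty test split")
    model = trained.model
    x = _stack_embeddings(trained.embeddings, test_ids, model.branch_order)
    with nn.no_grad():
        logits, _, _ = model.head_forward(x, training=False)
    p_mal = nn.softmax(logits)[:, 1]
    y = dataset.y(test_ids)
    return evaluate_predictions(y, p_mal, ids=test_ids)


# ------------------------------------------------------------------ CV / t-SNE

def cross_validate(store: FeatureStore, k: int, spec: FusionModelSpec,
                   hyperparams: Hyperparams, seed: int = 0) -> dict:
    """Stratified k-fold cross-validation with per-fold codebook refitting.

    Each image is tested exactly once; within each fold the training portion
    is further split 3:1 into train/validation for checkpoint selection, and
    all encoders are refitted on that fold's inner training ids only.
    """
    labels = store.labels
    ids = sorted(labels)
    y = np.array([labels[i] == MALIGNANT for i in ids], dtype=int)
    counts = [int((y == 0).sum()), int((y == 1).sum())]
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(counts) < k:
        raise ValueError(f"k={k} exceeds the smallest class count {min(counts)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports, memberships, encoder_fit_ids = [], {}, []
    fold_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=k)
    for fold, (train_idx, test_idx) in enumerate(skf.split(ids, y)):
        fold_seed = int(fold_seeds[fold])
        pool = [ids[j] for j in train_idx]
        test = tuple(ids[j] for j in test_idx)
        inner_train, inner_val = _stratified_two_way(pool, labels, 0.25,
                                                     fold_seed)
        splits = Splits(inner_train, inner_val, test, seed=fold_seed)
        encoders = fit_encoders(store, splits.train, seed=fold_seed)
        dataset = encode_dataset(store, encoders)
        model = build_fusion_model(FusionModelSpec(
            backbone=spec.backbone, concatenation=spec.concatenation,
            dropout=spec.dropout, seed=fold_seed, channels=spec.channels))
        hp = Hyperparams(**{**hyperparams.__dict__, "seed": fold_seed})
        trained = train_model(model, splits, hp, dataset)
        reports.append(evaluate_model(trained, test, dataset))
        encoder_fit_ids.append(encoders.fit_ids)
        for i in test:
            memberships[i] = fold
    return {"reports": reports, "fold_of": memberships,
            "fold_seeds": [int(s) for s in fold_seeds],
            "encoder_fit_ids": encoder_fit_ids}


def tsne_embed(feature_matrix: np.ndarray, labels=None, seed: int = 0) -> np.ndarray:
    """Seeded 2-D t-SNE embedding of a feature matrix (one point per row)."""
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or len(X) < 5:
        raise ValueError("need a 2-D matrix with at least 5 rows")
    perplexity = min(30.0, (len(X) - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, init="pca",
                perplexity=perplexity)
    return tsne.fit_transform(X)


# ---------------------------------------------------------------- experiments

SINGLE_ARMS = tuple(f"single:{c}" for c in HANDCRAFTED_CHANNELS + ("image",))
DEFAULT_ARMS = ("fused_concat", "fused_no_concat") + SINGLE_ARMS


def _arm_spec(arm: str, config: dict) -> FusionModelSpec:
    backbone = config["backbone"]
    seed = int(config.get("seed", 0))
    if arm == "fused_concat":
        return FusionModelSpec(backbone=backbone, concatenation=True, seed=seed)
    if arm == "fused_no_concat":
        return FusionModelSpec(backbone=backbone, concatenation=False, seed=seed)
    if arm.startswith("single:"):
        channel = arm.split(":", 1)[1]
        return FusionModelSpec(backbone=backbone, concatenation=False,
                               seed=seed, channels=(channel,))
    if arm.startswith("backbone:"):
        return FusionModelSpec(backbone=arm.split(":", 1)[1],
                               concatenation=True, seed=seed)
    raise ValueError(f"unknown experiment arm {arm!r}")


def run_experiment(config: dict, store: FeatureStore | None = None,
                   out_dir=None) -> dict:
    """Run a set of experiment arms on one shared dataset/split/seed.

    ``config`` keys: ``backbone`` (required), ``arms``, ``seed``, ``epochs``,
    ``batch_size``, ``augment_copies``, and (when ``store`` is not given)
    ``dataset = {n_per_class, image_size}``.  Every arm shares the dataset,
    the splits, the training-fitted encoders and -- because the trunk is
    frozen -- the per-image embeddings; arms differ only in their head
    architecture and training.
    """
    if "backbone" not in config:
        raise ValueError("experiment config is missing key 'backbone'")
    seed = int(config.get("seed", 0))
    arms = tuple(config.get("arms", DEFAULT_ARMS))
    epochs = int(config.get("epochs", 15))
    batch_size = int(config.get("batch_size", 16))
    augment_copies = int(config.get("augment_copies", 0))

    if store is None:
        ds_cfg = config.get("dataset", {})
        n_per_class = int(ds_cfg.get("n_per_class", 100))
        side = int(ds_cfg.get("image_size", 224))
        params = GenParams.for_size(side)
        manifest = generate_dataset(n_per_class, n_per_class, params, seed=seed)
        store = FeatureStore.from_manifest(manifest)
    store.extract()
    manifest = DatasetManifest(rows=[{"id": i, "label": img.label}
                                     for i, img in sorted(store.images.items())])
    splits = split_dataset(manifest, seed=seed)
    encoders = fit_encoders(store, splits.train, seed=seed)
    dataset = encode_dataset(store, encoders)
    assert_no_leakage(encoders, splits)

    extra_rows, extra_pairs = (), []
    if augment_copies > 0:
        feats, labs, origins = augment_training_features(
            store, dataset, splits.train, augment_copies, seed=seed)
        extra_rows = tuple(zip(feats, origins))
        extra_pairs = [(f"__aug_{j}", lab) for j, lab in enumerate(labs)]

    # one shared frozen embedder for all arms on the primary backbone
    embedder = build_fusion_model(FusionModelSpec(backbone=config["backbone"],
                                                  seed=seed))
    embeddings = compute_embeddings(embedder, dataset, splits.all_ids(),
                                    calibration_ids=splits.train,
                                    batch_size=batch_size,
                                    extra_rows=extra_rows)

    results, histories = {}, {}
    for arm in arms:
        spec = _arm_spec(arm, config)
        if spec.backbone != config["backbone"]:
            arm_embedder = build_fusion_model(FusionModelSpec(
                backbone=spec.backbone, seed=seed))
            arm_embeddings = compute_embeddings(
                arm_embedder, dataset, splits.all_ids(),
                calibration_ids=splits.train, batch_size=batch_size,
                extra_rows=extra_rows)
        else:
            arm_embeddings = embeddings
        model = build_fusion_model(spec)
        hp = Hyperparams(epochs=epochs, batch_size=batch_size, seed=seed)
        history, best_epoch = train_heads(model, arm_embeddings, dataset.labels,
                                          splits, hp,
                                          extra_train_rows=extra_pairs)
        trained = TrainedModel(model, arm_embeddings, history, best_epoch)
        results[arm] = evaluate_model(trained, splits.test, dataset)
        histories[arm] = history

    comparison = pd.DataFrame({arm: results[arm].to_dict() for arm in arms}).T
    bundle = {"results": results, "histories": histories, "splits": splits,
              "comparison": comparison, "dataset": dataset, "store": store}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comparison.drop(columns=["confusion"]).to_csv(out / "comparison.csv")
        (out / "metrics.json").write_text(json.dumps(
            {arm: results[arm].to_dict() for arm in arms}, indent=1))
        for arm in arms:
            histories[arm].frame().to_csv(out / f"history_{arm}.csv", index=False)
            r = results[arm]
            pd.DataFrame({"fpr": r.roc_fpr, "tpr": r.roc_tpr}).to_csv(
                out / f"roc_{arm}.csv", index=False)
    return bundle
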