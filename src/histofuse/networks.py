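"""The matching / integrated / fusion network assembly.

Architecture, in data-flow order:

* **Matching network** (one per hand-crafted channel): lifts a 1x1x50 encoded
  feature vector into a 224x224x3 pseudo-image through nine convolution
  blocks, each a fractional-stride (transposed) or stride-1 convolution
  followed by batch normalization and ReLU.  Spatial schedule
  1->7->14->28->56->112->224, channels 50->256->128->64->32->16->8->8->8->3.
* **Integrated network** (weights shared by all branches): a CNN backbone
  trunk plus an additional head of two 3x3 convolutions and one global
  average pooling, producing a 128-dim embedding.
* **Fusion network**: per-branch fully connected heads 128->84->42->2 with
  dropout 0.5 (a concatenating variant joins each hand-crafted embedding with
  the deep embedding first: 256->128->84->42->2); the eight softmaxed
  2-vectors are stacked into a length-16 prediction vector which a final
  fully connected layer maps to the two classes.

The loss supervises only the final 2-class output; branch softmaxes are
intermediate values (an auxiliary-loss option exists in the trainer but is
off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .datatypes import ALL_CHANNELS, CapabilityError, HANDCRAFTED_CHANNELS

EMBED_DIM = 128
HEAD_WIDTHS = (84, 42, 2)
MATCHING_CHANNELS = (256, 128, 64, 32, 16, 8, 8, 8, 3)
STACKED_PER_BRANCH = 2


@dataclass
class FusionModelSpec:
    """Architecture choices of one fusion model."""

    backbone: str = "resnet18"
    concatenation: bool = True
    dropout: float = 0.5
    pretrained: bool = False
    seed: int = 0
    channels: tuple = ALL_CHANNELS  # branches to build (subset allowed)

    def __post_init__(self) -> None:
        if self.backbone not in nn.SUPPORTED_BACKBONES:
            raise ValueError(f"unsupported backbone {self.backbone!r}; "
                             f"supported: {nn.SUPPORTED_BACKBONES}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        unknown = set(self.channels) - set(ALL_CHANNELS)
        if unknown or not self.channels:
            raise ValueError(f"channels must be a nonempty subset of "
                             f"{ALL_CHANNELS}, got {self.channels}")
        if self.pretrained:
            raise CapabilityError(
                "no pretrained backbone weights are bundled with this build; "
                "use pretrained=False (random initialization)")


@dataclass
class FeatureBundle:
    """The 7 encoded 50-dim vectors plus the raw RGB image for the DL branch."""

    features: dict  # channel name -> (50,) array
    image: np.ndarray | None = None  # (H, W, 3), uint8 or [0, 1] float

    def validate(self, channels=ALL_CHANNELS) -> None:
        for name in channels:
            if name == "image":
                if self.image is None:
                    raise ValueError("feature bundle is missing 'image'")
                continue
            vec = self.features.get(name)
            if vec is None:
                raise ValueError(f"feature bundle is missing {name!r}")
            if np.asarray(vec).shape != (50,):
                raise ValueError(f"feature {name!r} must have length 50")


@dataclass
class ClassProbabilities:
    """Final (benign, malignant) pair plus the per-branch prediction pairs."""

    probabilities: np.ndarray  # (2,), sums to 1
    branch_probabilities: dict  # channel name -> (2,)

    @property
    def p_malignant(self) -> float:
        return float(self.probabilities[1])


class MatchingNetwork(nn.Module):
    """Nine conv blocks lifting 1x1x50 -> 224x224x3 (trainable end-to-end)."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = (50,) + MATCHING_CHANNELS
        blocks = []
        # six fractional-stride blocks reach 224, three stride-1 blocks refine
        specs = [("convT", 7, 1, 0), ("convT", 4, 2, 1), ("convT", 4, 2, 1),
                 ("convT", 4, 2, 1), ("convT", 4, 2, 1), ("convT", 4, 2, 1),
                 ("conv", 3, 1, 1), ("conv", 3, 1, 1), ("conv", 3, 1, 1)]
        for (kind, k, s, p), cin, cout in zip(specs, chans[:-1], chans[1:]):
            conv = (nn.ConvTranspose2d(cin, cout, k, s, p, bias=False, rng=rng)
                    if kind == "convT"
                    else nn.Conv2d(cin, cout, k, s, p, bias=False, rng=rng))
            blocks.append(nn.Sequential(conv, nn.BatchNorm2d(cout), nn.ReLU()))
        self.blocks = blocks
        self.body = nn.Sequential(*blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:  # (N, 50) -> (N, 1, 1, 50)
            x = x[:, None, None, :]
        return self.body.forward(x, training)

    def backward(self, dy):
        dx = self.body.backward(dy)
        return dx[:, 0, 0, :] if dx.shape[1] == dx.shape[2] == 1 else dx


class IntegratedNetwork(nn.Module):
    """Backbone trunk + two 3x3 convolutions + global average pool -> 128."""

    def __init__(self, backbone: str = "resnet18", seed: int = 0):
        rng = np.random.default_rng(seed)
        self.trunk = nn.build_backbone(backbone, rng)
        ct = nn.TRUNK_CHANNELS[backbone]
        self.head = nn.Sequential(
            nn.Conv2d(ct, 256, 3, 1, 1, bias=False, rng=rng),
            nn.BatchNorm2d(256), nn.ReLU(),
            nn.Conv2d(256, EMBED_DIM, 3, 1, 1, bias=False, rng=rng),
            nn.BatchNorm2d(EMBED_DIM), nn.ReLU(),
            nn.GlobalAvgPool())
        self.backbone = backbone

    def forward(self, x, training=False):
        return self.head.forward(self.trunk.forward(x, training), training)

    def backward(self, dy):
        return self.trunk.backward(self.head.backward(dy))


def _branch_head(cin: int, dropout: float, rng) -> nn.Sequential:
    layers = []
    if cin != EMBED_DIM:  # concatenated input: extra 256 -> 128 layer
        layers += [nn.Linear(cin, EMBED_DIM, rng=rng), nn.ReLU(),
                   nn.Dropout(dropout, rng=rng)]
    widths = (EMBED_DIM,) + HEAD_WIDTHS
    for w_in, w_out in zip(widths[:-1], widths[1:]):
        layers.append(nn.Linear(w_in, w_out, rng=rng))
        if w_out != 2:
            layers += [nn.ReLU(), nn.Dropout(dropout, rng=rng)]
    return nn.Sequential(*layers)


class FusionModel(nn.Module):
    """Complete assembly: per-channel matching nets, one shared integrated
    network, per-branch heads and the final fusion layer."""

    def __init__(self, spec: FusionModelSpec):
        self.spec = spec
        root = np.random.SeedSequence(spec.seed)
        seeds = iter(root.generate_state(3 + 2 * len(spec.channels)))
        self.normalize = nn.Normalize()
        self.integrated = IntegratedNetwork(spec.backbone, seed=int(next(seeds)))
        self.matching = {
            name: MatchingNetwork(seed=int(next(seeds)))
            for name in spec.channels if name != "image"}
        self.heads = {}
        for name in spec.channels:
            cin = (2 * EMBED_DIM
                   if spec.concatenation and name != "image" and "image" in spec.channels
                   else EMBED_DIM)
            self.heads[name] = _branch_head(
                cin, spec.dropout, np.random.default_rng(int(next(seeds))))
        self.final = nn.Linear(STACKED_PER_BRANCH * len(spec.channels), 2,
                               rng=np.random.default_rng(int(next(seeds))))
        self.branch_order = tuple(spec.channels)

    # ------------------------------------------------------------ embeddings
    def embed_channel(self, name: str, batch: np.ndarray,
                      training: bool = False) -> np.ndarray:
        """128-dim embeddings for one branch.

        ``batch`` is (N, 50) encoded features for hand-crafted channels or
        (N, 224, 224, 3) images (uint8 or [0,1] float) for the DL branch.
        """
        if name == "image":
            x = np.asarray(batch, dtype=np.float32)
            if x.max() > 1.5:
                x = x / 255.0
            x = self.normalize.forward(x, training)
        else:
            x = self.matching[name].forward(np.asarray(batch), training)
            x = self.normalize.forward(x, training)
        return self.integrated.forward(x, training)

    # ------------------------------------------------------------- fusion FC
    def head_forward(self, embeddings: dict, training: bool = False):
        """Branch heads + final fusion layer on precomputed embeddings.

        Returns ``(final_logits, stacked_probs, branch_probs)`` where
        ``stacked_probs`` is the length-16 stacked prediction vector.
        """
        dl = embeddings.get("image")
        branch_probs = {}
        stacked = []
        self._head_cache = []
        for name in self.branch_order:
            emb = np.asarray(embeddings[name], dtype=np.float32)
            if (self.spec.concatenation and name != "image"
                    and "image" in self.branch_order):
                head_in = np.concatenate([emb, np.asarray(dl, dtype=np.float32)],
                                         axis=1)
            else:
                head_in = emb
            logits = self.heads[name].forward(head_in, training)
            probs = nn.softmax(logits)
            branch_probs[name] = probs
            stacked.append(probs)
            self._head_cache.append((name, probs, emb.shape[1]))
        stacked = np.concatenate(stacked, axis=1)  # (N, 2 * n_branches)
        final_logits = self.final.forward(stacked, training)
        return final_logits, stacked, branch_probs

    def head_backward(self, dfinal_logits: np.ndarray,
                      extra_dlogits: dict | None = None) -> dict:
        """Backprop through fusion layer + branch heads; returns per-branch
        gradients w.r.t. the embeddings (used for end-to-end fine-tuning).

        ``extra_dlogits`` optionally injects auxiliary per-branch logit
        gradients (deep-supervision option of the trainer).
        """
        dstacked = self.final.backward(dfinal_logits)
        demb = {name: 0.0 for name in self.branch_order}
        for i, (name, probs, emb_width) in enumerate(self._head_cache):
            dprobs = dstacked[:, 2 * i:2 * i + 2]
            dlogits = nn.softmax_backward(dprobs, probs)
            if extra_dlogits is not None and name in extra_dlogits:
                dlogits = dlogits + extra_dlogits[name]
            dhead_in = self.heads[name].backward(dlogits)
            if dhead_in.shape[1] > emb_width:  # concatenated branch
                demb[name] = demb[name] + dhead_in[:, :emb_width]
                demb["image"] = demb["image"] + dhead_in[:, emb_width:]
            else:
                demb[name] = demb[name] + dhead_in
        return demb

    def head_parameters(self) -> list:
        params = []
        for head in self.heads.values():
            params.extend(head.parameters())
        params.extend(self.final.parameters())
        return params

    # -------------------------------------------------------------- inference
    def classify_bundle(self, bundle: FeatureBundle) -> ClassProbabilities:
        bundle.validate(self.branch_order)
        embeddings = {}
        with nn.no_grad():
            for name in self.branch_order:
                if name == "image":
                    embeddings[name] = self.embed_channel("image",
                                                          bundle.image[None])
                else:
                    vec = np.asarray(bundle.features[name], dtype=np.float32)
                    embeddings[name] = self.embed_channel(name, vec[None])
            final_logits, _, branch_probs = self.head_forward(embeddings,
                                                              training=False)
        return ClassProbabilities(
            probabilities=nn.softmax(final_logits)[0],
            branch_probabilities={k: v[0] for k, v in branch_probs.items()})


def build_matching_network(seed: int = 0) -> MatchingNetwork:
    """A fresh nine-block matching network (1x1x50 -> 224x224x3)."""
    return MatchingNetwork(seed)


def build_integrated_network(spec: FusionModelSpec) -> IntegratedNetwork:
    """The shared backbone + additional-head network (image -> 128)."""
    return IntegratedNetwork(spec.backbone, seed=spec.seed)


def build_fusion_model(spec: FusionModelSpec) -> FusionModel:
    """Assemble matching + integrated + fusion networks per the spec."""
    return FusionModel(spec)


def classify(model: FusionModel, feature_bundle: FeatureBundle) -> ClassProbabilities:
    """Inference-mode class probabilities for one feature bundle."""
    return model.classify_bundle(feature_bundle)


def save_checkpoint(model: FusionModel, path) -> None:
    """Persist all weights (npz) plus a JSON architecture sidecar."""
    import json
    from pathlib import Path

    path = Path(path).with_suffix(".npz")
    state = model.state_dict()
    arrays = {f"p{i}": v for i, v in enumerate(state["params"])}
    for i, (mean, var) in enumerate(state["buffers"]):
        arrays[f"bm{i}"], arrays[f"bv{i}"] = mean, var
    np.savez(path, **arrays)
    sidecar = {"backbone": model.spec.backbone,
               "concatenation": model.spec.concatenation,
               "dropout": model.spec.dropout, "seed": model.spec.seed,
               "channels": list(model.spec.channels),
               "n_parameters": model.n_parameters()}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path) -> FusionModel:
    """Rebuild a FusionModel from :func:`save_checkpoint` output."""
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = FusionModelSpec(backbone=sidecar["backbone"],
                           concatenation=sidecar["concatenation"],
                           dropout=sidecar["dropout"], seed=sidecar["seed"],
                           channels=tuple(sidecar["channels"]))
    model = FusionModel(spec)
    data = np.load(path.with_suffix(".npz"))
    n_params = sum(1 for k in data.files if k[0] == "p")
    n_bns = sum(1 for k in data.files if k.startswith("bm"))
    state = {"params": [data[f"p{i}"] for i in range(n_params)],
             "buffers": [(data[f"bm{i}"], data[f"bv{i}"])
                         for i in range(n_bns)]}
    model.load_state_dict(state)
    return model
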