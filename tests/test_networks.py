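"""Architecture contracts of the matching / integrated / fusion networks."""

import numpy as np
import pytest

from histofuse import nn
from histofuse.datatypes import ALL_CHANNELS, CapabilityError
from histofuse.networks import (EMBED_DIM, FeatureBundle, FusionModelSpec,
                                build_fusion_model, build_integrated_network,
                                build_matching_network, classify)

RNG = np.random.default_rng(0)


def _random_bundle(seed=0):
    rng = np.random.default_rng(seed)
    features = {name: rng.random(50).astype(np.float32)
                for name in ALL_CHANNELS if name != "image"}
    image = rng.integers(0, 255, (224, 224, 3), dtype=np.uint8)
    return FeatureBundle(features=features, image=image)


# ---------------------------------------------------------- matching network

def test_matching_network_lifts_fifty_dims_to_image_shape():
    net = build_matching_network(seed=0)
    out = net.forward(RNG.random((2, 50)).astype(np.float32))
    assert out.shape == (2, 224, 224, 3)


def test_matching_network_has_nine_blocks_of_conv_bn_relu():
    net = build_matching_network(seed=0)
    assert net.n_blocks == 9
    for block in net.blocks:
        conv, bn, relu = block.layers
        assert isinstance(conv, (nn.Conv2d, nn.ConvTranspose2d))
        assert isinstance(bn, nn.BatchNorm2d)
        assert isinstance(relu, nn.ReLU)


def test_matching_network_is_differentiable_to_its_input():
    net = build_matching_network(seed=1)
    x = RNG.random((1, 50)).astype(np.float32)
    out = net.forward(x, training=True)
    dx = net.backward(np.ones_like(out))
    assert dx.shape == (1, 50)
    assert np.abs(dx).max() > 0


# --------------------------------------------------------- integrated network

def test_integrated_network_outputs_128(small_backbone_input=64):
    net = build_integrated_network(FusionModelSpec(backbone="resnet18"))
    with nn.no_grad():
        out = net.forward(RNG.random((2, small_backbone_input,
                                      small_backbone_input, 3)).astype(np.float32))
    assert out.shape == (2, EMBED_DIM)


def test_all_six_backbones_produce_128():
    for name in nn.SUPPORTED_BACKBONES:
        net = build_integrated_network(FusionModelSpec(backbone=name))
        with nn.no_grad():
            out = net.forward(RNG.random((1, 64, 64, 3)).astype(np.float32))
        assert out.shape == (1, EMBED_DIM), name


def test_unsupported_backbone_names_supported_set():
    with pytest.raises(ValueError, match="resnet18"):
        FusionModelSpec(backbone="alexnet")


def test_pretrained_weights_are_a_capability_error():
    with pytest.raises(CapabilityError, match="pretrained"):
        FusionModelSpec(backbone="resnet18", pretrained=True)


def test_dropout_rate_validation():
    with pytest.raises(ValueError, match="dropout"):
        FusionModelSpec(dropout=1.0)


# -------------------------------------------------------------- fusion model

def test_fusion_head_widths_follow_the_block_lengths():
    model = build_fusion_model(FusionModelSpec(concatenation=True, seed=0))
    for name in model.branch_order:
        linears = [l for l in model.heads[name].layers
                   if isinstance(l, nn.Linear)]
        shapes = [l.W.shape for l in linears]
        if name == "image":
            assert shapes == [(128, 84), (84, 42), (42, 2)]
        else:  # concatenated input widened to 256
            assert shapes == [(256, 128), (128, 84), (84, 42), (42, 2)]
    assert model.final.W.shape == (16, 2)


def test_no_concat_heads_take_128():
    model = build_fusion_model(FusionModelSpec(concatenation=False, seed=0))
    for name in model.branch_order:
        first = [l for l in model.heads[name].layers
                 if isinstance(l, nn.Linear)][0]
        assert first.W.shape == (128, 84)
    assert model.final.W.shape == (16, 2)


def test_stacked_prediction_vector_has_length_sixteen():
    for concat in (True, False):
        model = build_fusion_model(FusionModelSpec(concatenation=concat, seed=0))
        emb = {name: RNG.random((3, 128)).astype(np.float32)
               for name in model.branch_order}
        with nn.no_grad():
            logits, stacked, branch_probs = model.head_forward(emb)
        assert stacked.shape == (3, 16)
        assert logits.shape == (3, 2)
        for probs in branch_probs.values():
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_classify_probabilities_sum_to_one_and_are_deterministic():
    model = build_fusion_model(FusionModelSpec(seed=0))
    bundle = _random_bundle(3)
    a = classify(model, bundle)
    b = classify(model, bundle)
    assert a.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
    np.testing.assert_array_equal(a.probabilities, b.probabilities)
    assert set(a.branch_probabilities) == set(ALL_CHANNELS)
    for pair in a.branch_probabilities.values():
        assert pair.sum() == pytest.approx(1.0, abs=1e-6)


def test_classify_names_the_missing_feature():
    model = build_fusion_model(FusionModelSpec(seed=0))
    bundle = _random_bundle(4)
    del bundle.features["color"]
    with pytest.raises(ValueError, match="color"):
        classify(model, bundle)
    bundle2 = _random_bundle(4)
    bundle2.image = None
    with pytest.raises(ValueError, match="image"):
        classify(model, bundle2)


def test_dropout_randomizes_training_but_not_inference():
    model = build_fusion_model(FusionModelSpec(seed=0))
    emb = {name: RNG.random((4, 128)).astype(np.float32)
           for name in model.branch_order}
    with nn.no_grad():
        t1, _, _ = model.head_forward(emb, training=True)
        t2, _, _ = model.head_forward(emb, training=True)
        e1, _, _ = model.head_forward(emb, training=False)
        e2, _, _ = model.head_forward(emb, training=False)
    assert not np.array_equal(t1, t2)
    np.testing.assert_array_equal(e1, e2)


def test_permuting_branch_order_with_final_weights_is_invariant():
    model = build_fusion_model(FusionModelSpec(concatenation=False, seed=0))
    emb = {name: RNG.random((2, 128)).astype(np.float32)
           for name in model.branch_order}
    with nn.no_grad():
        base, _, _ = model.head_forward(emb, training=False)
    order = list(model.branch_order)
    perm = np.random.default_rng(1).permutation(len(order))
    model.branch_order = tuple(order[i] for i in perm)
    W = model.final.W.value.reshape(len(order), 2, 2)
    model.final.W.value = W[perm].reshape(len(order) * 2, 2)
    with nn.no_grad():
        permuted, _, _ = model.head_forward(emb, training=False)
    np.testing.assert_allclose(permuted, base, atol=1e-6)


def test_channel_subset_models_shrink_the_stack():
    model = build_fusion_model(FusionModelSpec(channels=("texture", "color"),
                                               concatenation=False, seed=0))
    emb = {name: RNG.random((2, 128)).astype(np.float32)
           for name in model.branch_order}
    with nn.no_grad():
        logits, stacked, _ = model.head_forward(emb)
    assert stacked.shape == (2, 4)
    assert logits.shape == (2, 2)


def test_checkpoint_round_trip(tmp_path):
    from histofuse.networks import load_checkpoint, save_checkpoint
    model = build_fusion_model(FusionModelSpec(
        channels=("texture", "image"), concatenation=False, seed=4))
    for p in model.parameters():  # make weights distinct from a fresh init
        p.value = p.value + 0.01
    save_checkpoint(model, tmp_path / "ckpt")
    loaded = load_checkpoint(tmp_path / "ckpt")
    assert loaded.spec == model.spec
    for a, b in zip(model.parameters(), loaded.parameters(), strict=True):
        np.testing.assert_array_equal(a.value, b.value)
    emb = {name: RNG.random((2, 128)).astype(np.float32)
           for name in model.branch_order}
    with nn.no_grad():
        la, _, _ = model.head_forward(emb)
        lb, _, _ = loaded.head_forward(emb)
    np.testing.assert_allclose(la, lb, atol=1e-6)


def test_shape_contract_through_the_whole_stack():
    """50 -> 224x224x3 -> 128 -> (84, 42, 2) -> 16 -> 2 for a batch of 20
    random feature vectors."""
    model = build_fusion_model(FusionModelSpec(seed=0))
    x = RNG.random((20, 50)).astype(np.float32)
    with nn.no_grad():
        lifted = model.matching["texture"].forward(x)
        assert lifted.shape == (20, 224, 224, 3)
        emb128 = model.integrated.forward(model.normalize.forward(lifted))
        assert emb128.shape == (20, 128)
        emb = {name: emb128 for name in model.branch_order}
        logits, stacked, branch = model.head_forward(emb)
    assert stacked.shape == (20, 16)
    assert logits.shape == (20, 2)
    probs = nn.softmax(logits)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
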