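"""Convolutional trunks (classifier-free) of the six supported backbones.

Each builder returns the feature trunk only -- global pooling and heads are
added by the integrated network.  Channel layouts follow the canonical
architectures: ResNet-18/50 (basic/bottleneck residual stages), VGG-11/16
(plain conv + maxpool stacks) and DenseNet-121/201 (dense blocks with growth
rate 32 and halving transitions).
"""

from __future__ import annotations

import numpy as np

from .layers import (AvgPool2d, BatchNorm2d, Conv2d, MaxPool2d, Module, ReLU,
                     Sequential, _rng, is_grad_enabled)

SUPPORTED_BACKBONES = ("resnet18", "resnet50", "vgg11", "vgg16",
                       "densenet121", "densenet201")

TRUNK_CHANNELS = {"resnet18": 512, "resnet50": 2048, "vgg11": 512,
                  "vgg16": 512, "densenet121": 1024, "densenet201": 1920}


def _conv_bn(cin, cout, k, stride, pad, rng):
    return Sequential(Conv2d(cin, cout, k, stride, pad, bias=False, rng=rng),
                      BatchNorm2d(cout))


class BasicBlock(Module):
    def __init__(self, cin, cout, stride, rng):
        self.main = Sequential(
            Conv2d(cin, cout, 3, stride, 1, bias=False, rng=rng),
            BatchNorm2d(cout), ReLU(),
            Conv2d(cout, cout, 3, 1, 1, bias=False, rng=rng),
            BatchNorm2d(cout))
        self.shortcut = (_conv_bn(cin, cout, 1, stride, 0, rng)
                         if stride != 1 or cin != cout else None)
        self.relu = ReLU()

    def forward(self, x, training=False):
        y = self.main.forward(x, training)
        s = x if self.shortcut is None else self.shortcut.forward(x, training)
        return self.relu.forward(y + s, training)

    def backward(self, dy):
        dsum = self.relu.backward(dy)
        dx = self.main.backward(dsum)
        if self.shortcut is None:
            return dx + dsum
        return dx + self.shortcut.backward(dsum)


class Bottleneck(Module):
    expansion = 4

    def __init__(self, cin, mid, stride, rng):
        cout = mid * self.expansion
        self.main = Sequential(
            Conv2d(cin, mid, 1, 1, 0, bias=False, rng=rng), BatchNorm2d(mid), ReLU(),
            Conv2d(mid, mid, 3, stride, 1, bias=False, rng=rng), BatchNorm2d(mid), ReLU(),
            Conv2d(mid, cout, 1, 1, 0, bias=False, rng=rng), BatchNorm2d(cout))
        self.shortcut = (_conv_bn(cin, cout, 1, stride, 0, rng)
                         if stride != 1 or cin != cout else None)
        self.relu = ReLU()

    forward = BasicBlock.forward
    backward = BasicBlock.backward


def _resnet(block, layers, widths, rng):
    modules = [Conv2d(3, 64, 7, 2, 3, bias=False, rng=rng), BatchNorm2d(64),
               ReLU(), MaxPool2d(3, 2, 1)]
    cin = 64
    for stage, (n, width) in enumerate(zip(layers, widths)):
        for i in range(n):
            stride = 2 if (stage > 0 and i == 0) else 1
            if block is BasicBlock:
                modules.append(BasicBlock(cin, width, stride, rng))
                cin = width
            else:
                modules.append(Bottleneck(cin, width, stride, rng))
                cin = width * Bottleneck.expansion
    return Sequential(*modules)


def _vgg(cfg, rng):
    layers, cin = [], 3
    for v in cfg:
        if v == "M":
            layers.append(MaxPool2d(2, 2))
        else:
            layers += [Conv2d(cin, v, 3, 1, 1, rng=rng), ReLU()]
            cin = v
    return Sequential(*layers)


class DenseLayer(Module):
    """BN-ReLU-1x1conv (bottleneck) - BN-ReLU-3x3conv, output concatenated."""

    def __init__(self, cin, growth, rng, bn_size=4):
        self.body = Sequential(
            BatchNorm2d(cin), ReLU(),
            Conv2d(cin, bn_size * growth, 1, 1, 0, bias=False, rng=rng),
            BatchNorm2d(bn_size * growth), ReLU(),
            Conv2d(bn_size * growth, growth, 3, 1, 1, bias=False, rng=rng))
        self.cin = cin

    def forward(self, x, training=False):
        new = self.body.forward(x, training)
        return np.concatenate([x, new], axis=-1)

    def backward(self, dy):
        dx, dnew = dy[..., :self.cin], dy[..., self.cin:]
        return dx + self.body.backward(np.ascontiguousarray(dnew))


def _densenet(block_config, rng, growth=32, init_ch=64):
    modules = [Conv2d(3, init_ch, 7, 2, 3, bias=False, rng=rng),
               BatchNorm2d(init_ch), ReLU(), MaxPool2d(3, 2, 1)]
    ch = init_ch
    for b, n_layers in enumerate(block_config):
        for _ in range(n_layers):
            modules.append(DenseLayer(ch, growth, rng))
            ch += growth
        if b != len(block_config) - 1:
            modules += [BatchNorm2d(ch), ReLU(),
                        Conv2d(ch, ch // 2, 1, 1, 0, bias=False, rng=rng),
                        AvgPool2d(2, 2)]
            ch //= 2
    modules += [BatchNorm2d(ch), ReLU()]
    return Sequential(*modules)


def build_backbone(name: str, rng=0) -> Module:
    """Instantiate a supported trunk; raises on unknown names."""
    rng = _rng(rng)
    if name == "resnet18":
        return _resnet(BasicBlock, [2, 2, 2, 2], [64, 128, 256, 512], rng)
    if name == "resnet50":
        return _resnet(Bottleneck, [3, 4, 6, 3], [64, 128, 256, 512], rng)
    if name == "vgg11":
        return _vgg([64, "M", 128, "M", 256, 256, "M",
                     512, 512, "M", 512, 512, "M"], rng)
    if name == "vgg16":
        return _vgg([64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
                     512, 512, 512, "M", 512, 512, 512, "M"], rng)
    if name == "densenet121":
        return _densenet((6, 12, 24, 16), rng)
    if name == "densenet201":
        return _densenet((6, 12, 48, 32), rng)
    raise ValueError(f"unsupported backbone {name!r}; "
                     f"supported: {SUPPORTED_BACKBONES}")
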