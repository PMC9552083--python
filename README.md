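# histofuse

Fusing hand-crafted and deep-learning features to classify H&E-stained
prostate pathology images as **benign** or **malignant**.

Pathologists read prostate biopsies through a handful of morphological
signals: benign glands have large lumens with papillary (finger-like)
in-folds and a bilayer epithelial rim, while cancer shows many small
smooth-walled lumens, enlarged pleomorphic nuclei with prominent nucleoli,
and disordered texture.  `histofuse` encodes those signals as seven
hand-crafted feature channels — GLCM nucleus texture, Fourier nucleus shape,
cavity-restricted unnormalized HOG, SIFT/SURF/ORB keypoints, and a color
auto-correlogram — compresses each into a 50-dim bag-of-visual-words +
TF-IDF vector, and fuses them with a CNN feature inside one network:

```
encoded 1x1x50 --matching net (9 conv blocks)--> 224x224x3 ---+
                                                              |--> integrated net
raw RGB image  ----------------------------------------------+    (backbone + 2 convs
                                                                   + avg pool) --> 128
8 x 128 --heads 128->84->42->2 (dropout 0.5)--> 8 softmax pairs
       --stack--> 16 --fc--> (p_benign, p_malignant)
```

With *concatenation*, each hand-crafted 128-vector is joined with the deep
128-vector before its head (256->128->84->42->2).  Supported backbones:
ResNet-18/50, VGG-11/16, DenseNet-121/201.  Two feature-space augmentation
algorithms perturb training vectors (integer ceil-Gaussian noise for
codeword counts; a shifted-sigmoid squash for color features).  Everything —
including the conv/batchnorm/SGD layer library — runs on numpy, on one CPU.

Because clinical datasets are private, the package ships a seeded synthetic
H&E generator that renders the same diagnostic structures (with per-image
ground truth for every nucleus and lumen), so the whole pipeline is testable
end to end.  See `docs/methods.md` for the model, parameters and
limitations.

## Worked example

```python
import histofuse as hf

# a labeled synthetic image + its ground truth
params = hf.GenParams.for_size(224)
image, gt = hf.generate_image("malignant", params, seed=1)
print(gt.n_lumens, gt.n_nuclei)          # 17 159

cavities = hf.segment_cavities(image)
print(cavities.n_regions)                 # 17  (matches ground truth)

regions = hf.segment_nuclei(image)
texture, shape = hf.nucleus_descriptors(image, regions)
print(texture.values.shape, shape.values.shape)   # (159, 6) (159, 60)

feat = hf.color_autocorrelogram(image)
print(feat.shape, feat.min() >= 0, feat.max() <= 1)   # (50,) True True
```

A 17-lumen, 159-nucleus malignant field versus the benign default of 2–4
large lumens: that count/size gap, plus the nucleus-size variance, is the
class signal every downstream feature picks up.

Running the ten-arm comparison (fused with/without concatenation and each
feature alone) on the seeded 200-image benchmark:

```python
from histofuse.pipeline import run_experiment
bundle = run_experiment({"backbone": "resnet18", "seed": 0, "epochs": 15,
                         "batch_size": 16,
                         "dataset": {"n_per_class": 100, "image_size": 224}})
print(bundle["comparison"][["accuracy", "auc"]])
```

prints (one CPU, ~11 min):

```
                accuracy     auc
fused_concat         1.0     1.0
fused_no_concat      1.0     1.0
single:texture       0.5  0.4725
single:shape       0.925   0.965
single:cavity        1.0     1.0
single:sift          0.5  0.5625
single:surf          0.5  0.4325
single:orb           0.5  0.4725
single:color         0.5  0.4325
single:image         0.5   0.625
```

The fused model reaches perfect test accuracy on this (deliberately
well-separated) synthetic benchmark while most single-feature arms fail to
converge within the 15-epoch recipe — the fusion benefit the architecture
was designed for, reproduced at desk scale.

There is also a thin CLI: `histofuse synth | extract | encode | train |
evaluate | cv | experiment` (each takes `--seed`, most take a YAML
`--config`).

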