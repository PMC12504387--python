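# camricap

CAM-guided four-image mixing augmentation for leaf-disease image
classification.

## The problem

Data-mixing augmentations such as RICAP (random image cropping and
patching) crop rectangles from four training images, tile them into one
composite, and mix the four labels in proportion to patch area.  On plant
leaf images the class evidence — the lesion, spot or streak — is small and
localised, so a random crop frequently contains none of it while the mixed
label still credits that source: label noise that misleads training.

`camricap` implements the attention-guided variant of this idea.  For each
source image a class activation map (CAM)

    Cam(x) = Σ_l  w_y[l] · F_l(x)

is formed from the last convolutional layer's feature maps `F_l` and the
classifier weights `w_y` of the image's own class.  The crop is centred on
the CAM argmax (mapped from the `h×w` feature grid back to pixels and
clamped inside the image with its size preserved), so each patch is a
*discriminative region*.  The composite's soft label weighs source `i` by
the share of its CAM mass the patch carries,

    λ_i ∝ Σ_{p ∈ P_i} Φ(Cam(x_i))_p  /  Σ_p Φ(Cam(x_i))_p ,    Σ_i λ_i = 1,

where `Φ` bilinearly upsamples the map to image resolution.  A patch that
captures all of its source's saliency gets full credit; one that captures
background gets almost none.

The package is aimed at people studying mixing augmentations at small
scale: every stage (CAM, peak, region, composition, label mixing, soft-label
training, evaluation) is an importable, tested function, and a synthetic
leaf-image generator with *planted* lesions makes localisation claims
checkable without downloads or GPUs.

## What's in the box

- `camricap.cam` — CAM computation, argmax localisation, coordinate
  mapping, bilinear upsampling, rectified activation mass.
- `camricap.regions` — crop-ratio sampling, size-preserving boundary
  clamping, cropping.
- `camricap.compose` — `enhanced_ricap` (CAM-guided mixing), `classic_ricap`
  (area-weighted baseline), label weighting and soft-label construction.
- `camricap.adapters` — the model contract (`features`, `class_weights`,
  `predict_logits`) with three implementations: a trainable numpy CNN, an
  analytic adapter whose CAM peaks sit on the planted lesions, and a
  constant-CAM adapter.
- `camricap.train` — soft-label cross-entropy training loop with warm-up
  epochs, confusion-matrix evaluation, per-class precision/recall/F1.
- `camricap.synthetic` — the planted-lesion leaf-image generator and
  manifest I/O.
- `camricap` CLI — `make-synth`, `augment`, `visualize-cam`, `train-demo`,
  `evaluate`, all reproducible from a resolved config.
- `examples/` — four short narrative scripts, one per capability.

## Worked example

```python
import numpy as np
from camricap import (SyntheticSpec, AugmentConfig, analytic_cam_provider,
                      enhanced_ricap, generate_samples)

spec = SyntheticSpec(num_classes=3, seed=0)          # 224x224 leaves
dataset, _ = generate_samples(10, spec)
batch = [dataset.samples[i] for i in (0, 1, 2, 10, 11, 12, 20, 21)]
mixed = enhanced_ricap(batch, analytic_cam_provider(spec),
                       AugmentConfig(0.25, 0.75), np.random.default_rng(42), 3)
for m in mixed[:2]:
    print([round(l, 3) for _, _, l in m.provenance], np.round(m.soft_label, 3))
```

prints

```
[0.259, 0.257, 0.225, 0.259] [0.484 0.516 0.   ]
[0.195, 0.27, 0.267, 0.268] [0.462 0.27  0.268]
```

Each composite drew four sources; the λ values are each source's captured
share of its own CAM mass (near 0.25 here because every crop covers its
lesion), and the soft label accumulates λ per class — always a probability
vector.  `examples/03_train_with_enhanced_ricap.py` continues the story:
training the bundled CNN for 5 epochs (2 clean warm-up + 3 mixed) prints
epoch losses falling from 1.084 to 0.851 and a clean-image test accuracy of
0.867 on seed 0 (seeds 0–2 average 0.944).

The same pipeline from the shell:

```
camricap make-synth --out-dir data --n-per-class 100
camricap augment    --manifest data/manifest.csv --out-dir composites --n 8
camricap train-demo --manifest data/manifest.csv --out-dir run \
                    --learning-rate 0.003 --augmentation enhanced_ricap
```

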