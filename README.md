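# remshuffle

A lightweight channel-shuffle CNN toolkit for recognizing plant leaf diseases
in cluttered field images, aimed at models small enough for mobile and
edge deployment. It implements the **REM-ShuffleNetV2** architecture family —
a ShuffleNetV2 backbone with re-tuned stage widths, **R**esidual shortcuts,
**E**fficient dual channel attention (EDCA) and **M**ulti-scale feature
extraction — together with the full experimental harness around it: dataset
manifests with a stratified 8:2 split and per-class augmentation expansion,
the SGD/cosine-annealing training recipe, a precision/recall/F1/accuracy
metric suite with per-crop aggregation, robustness corruptions, and a
deterministic synthetic leaf-image generator so every stage is testable at
desk scale. The network runs on a compact numpy autodiff core included in
the package, so there are no deep-learning framework dependencies.

## The model

ShuffleNetV2 processes features in units that split the channels in half,
pass one half through a 1×1 → depthwise 3×3 → 1×1 convolution branch,
re-concatenate and then *shuffle* the channels (a fixed interleaving
permutation) so information mixes across branches. The REM variant modifies
the stock network in four ways:

* **Architecture tuning** — stage repeats [2, 3, 2] and output channels
  [96, 192, 384, 1024] instead of [3, 7, 3] / [116, 232, 464, 1024],
  cutting the parameter count substantially at negligible accuracy cost.
* **Residual structure** — an identity shortcut in each basic unit and a
  projected shortcut in each downsampling unit (3×3 max pool stride 2 +
  1×1 conv by default; average-pool and full-conv variants are provided).
* **EDCA** — each channel *c* of a feature map X (H×W×C) is summarized by
  its spatial mean A_c = (1/HW)ΣΣ X_c(h,w) and standard deviation
  S_c = √((1/HW)ΣΣ (X_c−A_c)²); each descriptor passes through its own
  bias-free 1-D convolution of adaptive size
  K = |log₂(C)/γ + b/γ|_odd (γ=2, b=1), and the channel weights are
  ω = σ(C1D_K(y₁) + C1D_K(y₂)), multiplied back onto X. SE, ECA and SRM
  comparators are included. EDCA adds only 2K parameters per insertion.
* **Multi-scale blocks** — MSFEM, a stem mixing a max-pool branch with a
  stacked-conv branch (stride 4 overall, 24 channels out), and MDFEM,
  parallel 3×3/5×5 branches fused by a 1×1 conv after the last stage.

Training follows the standard recipe: SGD (momentum 0.9, weight decay 5e-4
on conv/linear weights), batch size 32, cross-entropy over softmax, cosine
annealing of the learning rate from 0.01 to 1e-9, best-checkpoint selection
on test accuracy.

## Worked example

Train a desk-scale model with every REM feature enabled on the built-in
synthetic 4-class leaf dataset (healthy + three lesion types on cluttered
backgrounds, 100 train / 25 test images per class at 64×64 px):

```python
import numpy as np
from remshuffle import build_model, tiny_preset, easy_spec, train, TrainConfig, evaluate
from remshuffle.synth import generate_arrays

xtr, ytr, xte, yte, classes = generate_arrays(easy_spec(seed=0))
model = build_model(tiny_preset(num_classes=4, input_size=64), seed=0)
history = train(model, (xtr, ytr), (xte, yte), TrainConfig(epochs=10, seed=0), verbose=True)
print(evaluate(model, xte, yte).summary_row())
```

which prints (about a minute on one CPU):

```
epoch   0  lr 0.010000  loss 0.8938  test acc 0.9200
epoch   1  lr 0.009755  loss 0.2001  test acc 1.0000
...
epoch   9  lr 0.000245  loss 0.0145  test acc 1.0000
{'precision_pct': 100.0, 'recall_pct': 100.0, 'f1_pct': 100.0, 'accuracy_pct': 100.0}
```

The loss trace shows the untrained network starting near chance
(−ln(1/4) ≈ 1.386) and converging within two epochs; the four synthetic
classes are separable by their lesion color/count/size signatures alone, so
a correctly wired model should reach perfect test accuracy. Parameter
accounting for the named configurations:

```
$ remshuffle build-info
          config  params   fp32_mb
shufflenetv2_1.0 1276154  4.868141
  tuned_baseline  793990  3.028831
             rem 3557278 13.569939
        rem_tiny  230608  0.879700
```

The same CLI exposes `synth`, `split`, `augment`, `perturb`, `train` and
`eval` subcommands over class-per-folder image trees and CSV manifests.

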