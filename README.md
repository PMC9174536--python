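# angioseg

Lightweight coronary-artery segmentation for X-ray angiograms.

Coronary angiography is the clinical gold standard for diagnosing coronary
artery disease: a radio-opaque contrast agent renders the arteries as dark
curvilinear trees on a noisy, unevenly illuminated X-ray frame. Segmenting
those vessels pixel-by-pixel supports stenosis assessment, but the heavy
encoder–decoder networks that dominate the task are impractical on modest
hardware. `angioseg` implements a *lightweight* alternative for researchers
and engineers studying efficient medical-image segmentation: a U-Net variant
whose stages are MobileNetV2-style **bottleneck residual blocks**
(1×1 expand ×t → 3×3 depthwise → 1×1 linear project, residual when stride 1
and widths match), with two cheap attention mechanisms:

- a **patch attention module (PAM)** after the deepest encoder map —
  softmax self-attention `s_mn = exp(q_m·k_n) / Σ_n' exp(q_m·k_n')` computed
  over non-overlapping n×n patches instead of pixels, shrinking the attention
  matrix by a factor of n⁴;
- **squeeze-and-excitation (SE)** channel gates inside every bottleneck
  block (global average pool → FC/ReLU → FC/sigmoid → per-channel rescale).

Training minimizes a class-weighted cross-entropy plus Dice objective,

```
L = L_WCE + β·L_Dice,   w = 1 − Σy/(H·W),
L_WCE = −mean(α·w·y·log p + (1−w)·(1−y)·log(1−p))
```

with α = 0.2, β = 0.01, Adam (β₁ = 0.9, weight decay 1e-4) and the poly
schedule `lr = base_lr·(1 − iter/max_iter)^0.9`, base_lr 4e-3. Evaluation
reports sensitivity, specificity, accuracy and AUC over pooled test pixels.
A morphological **top-hat** enhancer (`F + whitetophat(F) − blacktophat(F)`)
and **CLAHE** are provided as mutually exclusive preprocessing strategies.

Everything runs on the CPU: the network and its training loop are built on a
small numpy reverse-mode autodiff engine shipped inside the package, and a
seeded synthetic angiogram generator produces realistic phantom fixtures
(connected branching trees at 3–10 % vessel fraction, nonuniform
illumination, noise) so no clinical data is needed to exercise the code.

With the default frozen layout the plain backbone holds **0.65 M** trainable
parameters at expansion factor t = 2 (1.13 / 1.61 / 2.09 M at t = 4/6/8);
SE gates add 0.02 M, PAM adds 0.08 M, and the full model holds **0.75 M**.

## Worked example

```sh
angioseg synth --n 4 --size 96 --seed 5 --out-dir data/
angioseg train --data-dir data/ --out-dir run/ --seed 5 \
               --max-iter 300 --batch-size 4
angioseg evaluate --checkpoint run/checkpoint --data-dir data/ --out-dir run/
angioseg params --t 2 --pam --se
```

`synth` writes four 96×96 phantom angiogram/mask pairs plus a manifest.
`train` fits the full model (t = 2, PAM, SE) with random
rotation/crop/flip augmentation, logging per-iteration loss and learning
rate to `run/history.csv` (loss 0.056 → 0.003 over the 300 iterations, a
few minutes on one CPU core). `evaluate` then prints

```json
{
  "sensitivity": 0.9927652733118971,
  "specificity": 0.9922515440763616,
  "accuracy": 0.9922688802083334,
  "auc": 0.9997000086659649,
  "counts": {"tp": 1235, "tn": 35344, "fp": 276, "fn": 9},
  "undefined": []
}
```

— on its own 4-image training fixture the 0.75 M-parameter model detects
99.3 % of vessel pixels at 99.2 % specificity (the all-background accuracy
baseline is 0.96), confirming the architecture, objective and optimizer
wiring end-to-end. Trained without augmentation the same run overfits to
Dice 1.0; the test suite asserts that experiment. `params` prints
`749107 (0.75 M)`, the exact trainable-scalar count of the full model.

The same API is available from Python:

```python
from angioseg import make_fixture, build_network, NetConfig, TrainConfig, train, evaluate

pairs = make_fixture(n=4, size=96, seed=1)
net = build_network(NetConfig(), seed=3)
net, history = train(net, pairs, TrainConfig(max_iter=300, batch_size=4, seed=7, augment=None))
print(evaluate(net, pairs).to_dict())
```

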