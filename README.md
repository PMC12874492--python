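# mfsunet

Segmentation of thyroid nodules in 2-D grayscale ultrasound is hard for
reasons intrinsic to the modality: multiplicative speckle, acoustic
shadows, nodules whose size spans millimetres to centimetres, boundaries
that fade into surrounding tissue, and reference annotations that wobble
slightly between expert readers.  `mfsunet` is a self-contained
implementation of an encoder–decoder network built around three operators
that target exactly these problems, together with the full training /
evaluation pipeline and a synthetic speckle-phantom generator so that
everything is testable on one CPU without downloading clinical data.

The three operators, each independently usable and tested:

* **Multi-Path Vision Mamba (MPV)** — the feature map X ∈ ℝ^{H×W×C} is
  layer-normalised, flattened along four directional scan paths (row- and
  column-raster, forward and backward), and each sequence is processed by
  a selective state-space model, the discretised linear recurrence

      h_t = exp(Δ_t A) ⊙ h_{t−1} + Δ_t B_t x_t,   y_t = ⟨C_t, h_t⟩,

  with input-dependent (Δ, B, C).  This captures global context in
  linear time.  Branch outputs re-enter the grid with learnable residual
  scales β_i, are concatenated, normalised and projected back to C.
* **Feature Gating (FG)** — an attention gate on every skip connection:
  α = σ(ψᵀ ReLU(W_x x^l + W_g g_up + b) + b_ψ) ∈ (0,1) reweights the
  encoder feature x^l using the deeper decoder signal g, suppressing
  background clutter before fusion.
* **Supervised Label Rectification (SLR)** — during training, the pixels
  where the current hard prediction disagrees with the label form a mask
  M, and decoder features are mixed punitively,
  F_out = F_dec + (1−λ)·F_dec⊙(1−M) − λγ·F_dec⊙M (defaults λ=0.5, γ=1.0),
  damping responses in boundary-ambiguous, label-noisy regions.  SLR is a
  strict pass-through at inference.

Evaluation covers Dice, IoU, precision, sensitivity, the symmetric
95th-percentile Hausdorff distance (HD95), and a paired t-test harness.
Because no autodiff framework is a dependency, the package carries a
small tape-based reverse-mode engine on numpy with numba-jitted scan
kernels; see `docs/methods.md` for the model, conventions and
limitations.

## Worked example

```python
import numpy as np
from mfsunet import (NetworkConfig, PhantomConfig, TrainConfig,
                     evaluate, generate_dataset, train)

data = PhantomConfig(image_size=64)                  # speckled phantoms
tr, va, te = generate_dataset(data, 64, seed=100)    # patient-grouped 80/10/10
net = NetworkConfig(depth=2, base_width=8, ssm_state_dim=4, ssm_expand=1,
                    seed=0)
run = TrainConfig(epochs=30, batch_size=8, lr=1e-2, augment=False,
                  early_stop_dice=0.88, seed=0)
res = train(run, net, tr, va)
print(f"best val Dice {res.best_val_dice:.3f} at epoch {res.best_epoch}")
table = evaluate(res.net, te, train_patient_ids={s.patient_id for s in tr})
print(table.tail(1).to_string())
```

Output from this exact script:

```
best val Dice 0.890 at epoch 5
                        dice                iou          precision        sensitivity               hd95
sample_id
mean ± sd  0.8604 (± 0.0111)  0.7552 (± 0.0171)  0.9989 (± 0.0027)  0.7558 (± 0.0177)  1.9004 (± 0.2140)
```

`best val Dice 0.890` is the best validation Dice the two-stage width-8
model reached within 30 epochs (training stops early once 0.88 is
exceeded); the final row of the metric table is the held-out test-split
mean ± sd — overlap metrics are fractions in [0, 1], HD95 is in pixels.
Evaluation verifies patient-level split hygiene and raises if a test
patient appears in the training set.

The same workflow is available from the shell:

```bash
mfsunet generate --out data/ --n 100 --size 64 --seed 0
mfsunet train --data data/ --out run/ --epochs 30 --lr 0.01 --seed 0
mfsunet evaluate --data data/ --checkpoint run/checkpoint --split test
mfsunet predict --checkpoint run/checkpoint --image data/image/patient0000_000.png --out mask.png
mfsunet ablate --data data/ --out ablation.csv        # baseline / w/o F&S / w/o S / full
mfsunet gridsearch --data data/ --out grid.csv        # 5x5 (lambda, gamma) sweep
```

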