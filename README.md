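# paraseg

Automatic segmentation of the lumbar paraspinal muscles — left and right
multifidus, erector spinae and psoas major — from axial T2-weighted MRI,
with the evaluation and reliability machinery needed to compare model
variants the way a clinical segmentation study does.

The package is aimed at researchers quantifying paraspinal muscle size and
composition who want to replace ~35-minute manual segmentations with a
trained network, and at anyone who needs the full harness around such a
model: preprocessing, augmentation, training, metrics and statistics.

## What's inside

* **Modified U-Net** (2D and 3D, numpy forward/backward): residual stages
  of `conv → instance norm → leaky ReLU` pairs, stride-2 convolutions
  instead of pooling, stride-2 transpose convolutions with concatenated
  skip connections, and an optional deeper 512-filter level. Trained with
  DiceCE (soft Dice + cross-entropy) and AdamW (lr 1e-3, decoupled weight
  decay 1e-4) on class-balanced windows (foreground-centred with
  probability ½). Exposed as a scikit-learn style estimator
  (`UNetSegmenter.fit/predict`).
* **Seven agreement metrics** per muscle from voxel confusion counts —
  Sørensen-Dice `2|SM∩GT|/(|SM|+|GT|)`, Jaccard, conformity
  `1−(FP+FN)/TP`, TPR, TNR, PPV, volume ratio `|SM|/|GT|` — plus absolute
  volumes in ml.
* **Reliability statistics**: ICC(2,1) with exact F-based 95% CI,
  Bland–Altman limits of agreement, fully factorial repeated-measures
  ANOVA with Mauchly/Shapiro–Wilk/skewness/kurtosis assumption checks, and
  post-hoc paired t-tests.
* **Augmentation**: random affine (±2.5% scale, ±2.5° physical-space
  rotation, ±25/±25/±2-voxel translation, left–right mirroring with the
  anatomically required label swap) plus elastic deformation
  (σ ∈ [6, 8], magnitude ∈ [50, 100], border padding), expanding a
  training set offline to a fixed 1000 pairs by default.
* **Synthetic phantom generator**: lumbar-like labelled volumes with the
  cohort's volume ordering (erector spinae > psoas > multifidus), T2-like
  contrast, intramuscular fat speckle, bias field and noise — so the whole
  pipeline runs and is tested without patient data.

## Worked example

Train a small 2D model on 8 synthetic subjects and evaluate a held-out one:

```python
from paraseg import (PhantomConfig, generate_phantom, normalize_intensity,
                     UNetSegmenter, compute_metrics, icc_2_1)

cfg = PhantomConfig()                       # 64x64x12 phantoms
pairs = [generate_phantom(cfg, s) for s in range(9)]
X = [normalize_intensity(img) for img, _ in pairs]
y = [msk for _, msk in pairs]

est = UNetSegmenter(dims=2, channels=(8, 16, 32, 64), iterations=300,
                    batch_size=8, num_samples=4, window=(64, 64, 1), seed=0)
est.fit(X[:8], y[:8])

pred = est.predict([X[8]])[0]
report = compute_metrics(pred, y[8])
print(report[["label_name", "dice", "volume_sm_ml", "volume_gt_ml"]]
      .to_string(index=False))
```

Output (300 iterations, seed 0):

```
          label_name     dice  volume_sm_ml  volume_gt_ml
     multifidus_left 0.969146     18.215496     19.249776
    multifidus_right 0.971132     18.264168     19.249776
 erector_spinae_left 0.985503     39.850200     39.886704
erector_spinae_right 0.985079     40.239576     39.679848
          psoas_left 0.990519     21.659040     21.975408
         psoas_right 0.988914     21.829392     22.072752
```

Each row is one muscle on the held-out subject: `dice` is the voxel
overlap with the ground truth (1.0 = perfect), and the two volume columns
compare the predicted and true muscle volumes in millilitres — the
quantities a clinical study would feed into ICC and Bland–Altman analyses.
Even this 300-iteration toy model exceeds 0.96 Dice on the high-contrast
phantoms; longer training pushes it higher.

The same pipeline is scriptable from the shell:

```bash
paraseg phantom --out-dir cohort --n 24 --seed 0
paraseg experiment config.yaml        # phantom -> train -> metrics -> stats
paraseg evaluate pred.nii.gz gt.nii.gz
```

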