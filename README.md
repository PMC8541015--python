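# cascadeseg

Coarse-to-fine segmentation of the liver and liver tumors in abdominal CT.

Accurate delineation of the liver and its lesions on CT is a prerequisite for
surgical planning and follow-up in hepatic oncology, but lesions are small,
low-contrast and irregular, and tumor pixels are a vanishing fraction of an
abdominal scan. `cascadeseg` implements a two-stage cascade for this problem:

1. **Coarse stage** — a U-Net (contracting path with channel doubling,
   expanding path with skip concatenation, 23 convolutional layers at the
   default depth) produces an initial three-class probability map
   (background / liver / tumor) per axial slice.
2. **Fine stage** — the coarse foreground probability is fused with the
   min-max-normalised input by addition, and the fused map is presented at
   three resolutions (512/256/128 at native CT size). Each resolution branch
   applies a stem convolution, a **densely connected atrous-spatial-pyramid-
   pooling block** (each dilated 3×3 layer sees the concatenation of the
   block input and all previous layers' outputs; dilation rates 1, 3, 6, 12)
   and **multi-layered channel attention** (three convolution branches, each
   reduced by global max- and average-pooling, passed through a shared
   length-K channel-axis convolution, sigmoid-normalised, and used to rescale
   the channels). Branch features are bilinearly up-sampled, summed, and
   decoded by a final convolution + softmax.

Training uses an **adaptive weighted cross-entropy**: with class pixel
proportion `P_c` and hyper-parameter `t = 1.02`,

    w_c = 1 / ln(t + P_c),   clamped to [1, 50],

so rare classes (tumor) are up-weighted toward the clamp while background
stays near 1. Evaluation reports, per class and case,

    Dice = 2·TP / (2·TP + FP + FN)
    VOE  = 1 − TP / (TP + FP + FN)
    RVD  = FP / (TP + FN)        (signed variant (TP+FP)/(TP+FN) − 1 in tables)

stratified by lesion pattern: **large** (tumor > 10% of the liver region's
pixels), **small**, and **multiple** (≥ 2 disjoint lesions).

The networks run on a small NumPy reverse-mode autodiff engine included in
the package (`cascadeseg.nn`), so everything trains and predicts on a plain
CPU. A synthetic CT phantom generator emulates the relevant structure of
abdominal slices (HU calibration via slope/intercept, one bright liver
ellipse, darker lesions inside it, background clutter and noise), making the
entire pipeline testable without patient data.

## Worked example

Generate 60 phantoms at desk scale, train the cascade, and evaluate:

```sh
cascadeseg synth data/ --n-cases 60 --seed 7 --profile cpu-test
cascadeseg train data/ --run-dir runs/demo --seed 7 --profile cpu-test
cascadeseg predict data/ --checkpoint runs/demo/cascade.npz --out-dir preds/
cascadeseg evaluate preds/ data/
```

The same experiment through the library (this is what the test suite runs at
200 phantoms; numbers below are from this exact snippet):

```python
import numpy as np
from dataclasses import replace
from cascadeseg import (PhantomSpec, generate_arrays, split_dataset,
                        train_cascade, predict, predict_coarse, evaluate_run)
from cascadeseg.cascade_train import CPU_TEST_TRAIN
from cascadeseg.coarse_net import CPU_TEST_UNET
from cascadeseg.fine_net import CPU_TEST_ADENSE

mix = {"large": 0.3, "small": 0.3, "multiple": 0.3, "none": 0.1}
images, masks, patterns = generate_arrays(100, mix, PhantomSpec(image_side=64), seed=7)
(tr_i, tr_m, _), (va_i, va_m, va_p) = split_dataset(images, masks, 0.2, 7, patterns)
model, history = train_cascade(tr_i, tr_m, replace(CPU_TEST_TRAIN, seed=0),
                               CPU_TEST_UNET, CPU_TEST_ADENSE)
_, table = evaluate_run(predict(model, va_i), va_m, va_p)
print(table[table.pattern == "overall"].round(3).to_string(index=False))
```

```
pattern  n_cases  dice_liver  voe_liver  rvd_liver  dice_tumor  voe_tumor  rvd_tumor
overall       20       0.956      0.084      0.039       0.593      0.535        inf
```

On the same validation set the coarse stage alone (`predict_coarse`) reaches
liver Dice 0.940 and tumor Dice 0.257: the fused, multi-resolution refinement
mainly helps the small, low-contrast lesions, which is the point of the
cascade. The `inf` in the tumor RVD column is honest bookkeeping: one
validation phantom has no tumor at all, so any false-positive tumor pixel
makes the relative volume difference infinite, and the unweighted mean
inherits it (per-case tables show which case is responsible). Phantom
segmentation is far easier than clinical CT; these numbers characterise the
pipeline, not clinical performance.

## Layout

- `cascadeseg.io_preprocess` — NIfTI reading, HU calibration/windowing,
  Gaussian denoising, empty-slice filtering, PNG export.
- `cascadeseg.phantom` — synthetic phantom generator and the lesion-pattern
  classifier.
- `cascadeseg.coarse_net`, `cascadeseg.fine_net` — the two network stages.
- `cascadeseg.loss_metrics` — adaptive weighted cross-entropy, Dice/VOE/RVD,
  aggregation tables.
- `cascadeseg.cascade_train` — two-stage training, prediction, ablations,
  checkpoints.
- `cascadeseg.cli` — the `cascadeseg` command (preprocess / synth / train /
  predict / evaluate / ablate).
- `cascadeseg.nn` — the NumPy autodiff engine and layers.

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical choices.
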