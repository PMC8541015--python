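# Methods

## Problem and model

The package segments axial abdominal CT slices into background, liver and
tumor. A two-stage cascade narrows the problem: stage 1 (a U-Net) provides a
coarse localisation; stage 2 re-reads the image with that prior attached and
refines it, using dilated convolutions instead of pooling so spatial detail
survives, and channel attention to emphasise informative feature maps.

**Stage 1 — U-Net.** Per contracting level: two 3×3 convolutions + ReLU, then
2×2 max pooling with channel doubling. The expanding path uses 2×2 stride-2
transposed convolutions (halving channels), concatenation with the same-level
skip features, and two 3×3 convolutions; a 1×1 convolution maps to 3 classes.
Defaults depth 4, base width 64 (23 convolutional layers counting transposed
and 1×1 convolutions). All 3×3 convolutions use "same" padding so outputs
keep the input size (the classic design crops; same-size maps are required
here because stage 2 consumes them at full resolution). Softmax (not
per-class sigmoids) because the classes are mutually exclusive. No batch
normalisation by default.

**Fusion.** The stage-1 probability map is fused with the input by addition:
`fused = minmax(image) + P_liver + P_tumor`, a single channel. This keeps
stage 2's input single-channel like stage 1's; concatenation was the
alternative and is deliberately not used (addition keeps the "prior as
brightness boost" reading and the branch stems unchanged).

**Stage 2 — multi-resolution dense-ASPP with channel attention.** The fused
map is presented at scale factors (1, 2, 4): 512/256/128 pixels at native CT
size, via separable bilinear interpolation (half-pixel-centre convention).
Each branch: one 3×3 stem convolution to a common width, then a dense-ASPP
block, then channel attention. The dense-ASPP block chains 3×3 convolutions
with dilation rates (1, 3, 6, 12); layer *i* receives the concatenation of
the block input and all previous layer outputs (C + (i−1)·g channels, growth
rate g), and a final 1×1 projection returns to C channels. Rates must stay
below 24 — beyond that a dilated kernel samples too sparsely to be useful —
and the config enforces this. Channel attention forms three branches with
kernel sizes (1, 3, 5) ("three kinds of convolutions", the cheapest reading
of three context scales); each branch is reduced by global max- and
average-pooling to two C-vectors, both passed through one *shared* length-K
convolution along the channel axis (K = 3, the smallest odd kernel giving
cross-channel interaction), summed, and sigmoid-squashed into per-channel
weights that rescale the branch; the three calibrated branches are summed.
Branch outputs are bilinearly up-sampled to full resolution, summed (fusion
by addition, consistent with the cascade's fusion), and decoded by one 3×3
convolution + softmax. Whether the attention branches share their input
convolutions was an open choice; they are independent here.

**Loss.** Weighted cross-entropy, `L = −(1/N) Σ_i Σ_c w_c · 1[y_i = c] ·
ln p_ic`, with N the pixel count of the batch (pixel-normalised rather than
image-normalised; the two differ only by a constant for fixed image size).
Weights `w_c = 1/ln(t + P_c)`, t = 1.02, clamped to the closed interval
[1, 50]; the formula is written with per-pixel weights but only per-class
weights are defined, so class weights are broadcast over pixels. P_c is
computed once from the training split before training (a per-batch option
exists behind a flag in spirit but is not the default: dataset-level
imbalance is the stable signal). Probabilities are floored at 1e−12 inside
the log so degenerate predictions give a large finite loss.

**Training.** Adam (standard choice for this family; the method's constant
learning rate 1e−4 and 300 epochs are the config defaults), sequential:
stage 1 to completion, then stage 2 on the frozen stage-1 priors. An optional
joint phase optimises `alpha·L_coarse + (1−alpha)·L_fine` with alpha = 0.33
by default; "alpha" is interpreted as this loss-mixing coefficient — the only
reading that fits a scalar in (0,1) — held constant. During the joint phase
the stage-2 input is the *detached* coarse probability map: the stages couple
through the mixed objective only, which keeps each stage's gradients
well-defined and preserves the property that alpha = 1 sends no gradient to
stage 2. No data augmentation.

## Preprocessing

Raw scanner values convert to Hounsfield units by the affine calibration
HU = pixel·slope + intercept. The HU window defaults to (−200, +250) — a
standard liver window retaining parenchyma (≈ 40–70 HU) and hypodense
lesions while clipping air and most bone; it was never going to be derivable
from first principles, so it is a config key. Gaussian denoising uses
sigma = 1 px, kernel truncated at 3σ, reflective borders (preserves the
image mean). Slices whose masks contain no liver or tumor pixels are dropped
from training sets. PNG export maps the window linearly to 8-bit; mask PNGs
store labels verbatim so they round-trip exactly. NIfTI volumes are sliced
along the last stored axis with no reorientation.

## Evaluation

Per class (liver = 1, tumor = 2) and case: Dice = 2TP/(2TP+FP+FN),
VOE = 1 − TP/(TP+FP+FN), RVD. The unsigned form FP/(TP+FN) is non-negative
by construction, which cannot express under-segmentation; the signed form
(TP+FP)/(TP+FN) − 1 is therefore also computed and is what summary tables
report. When prediction and truth are both empty the case is scored as
perfect agreement (Dice 1, VOE 0, RVD 0). Aggregation is the unweighted mean
of per-case metrics, overall and per lesion pattern.

**Patterns.** A case is *multiple* with ≥ 2 disjoint lesion components
(8-connectivity in 2-D, 26 in 3-D — the standard blob-counting choice; the
multiplicity rule takes precedence over size), else *large* when
tumor_pixels / liver_region_pixels > 0.10, else *small*. The denominator is
the whole liver region (labels 1 ∪ 2), since lesions lie anatomically inside
the liver; exactly 10% is *small* ("greater than" is required for large).
Patterns are assigned per slice.

## Synthetic phantoms

Each phantom slice has one noisy-edged liver ellipse (semi-axes 22–34% of the
image side, sinusoidal boundary perturbation), zero or more disk lesions
strictly inside it (kept mutually disjoint so component counting is
unambiguous), low-frequency background clutter, and white acquisition noise.
Tissue attenuations: liver 60 ± 10 HU, tumor 30 ± 8 HU, background −100 HU,
noise SD 15 HU — a plausible portal-venous contrast ordering with hypodense
lesions. Raw voxels are stored as (HU − intercept)/slope (defaults slope 1,
intercept −1024) so the HU-calibration path is exercised. Pattern targets are
enforced by construction and verified by re-classification, with bounded
retries. What the phantoms do **not** emulate: other organs and vessels,
partial-volume effects, hyper-enhancing lesions, scanner-dependent noise
texture, and 3-D anatomical continuity — so passing tests demonstrate that
the pipeline's mechanics and learning dynamics work, not clinical accuracy.

## Desk-scale profile and problem sizes

The package's own experiments and tests run a reduced profile chosen once:
64×64 phantoms, U-Net depth 3 / base width 8, fine width and growth 8, Adam
at 3e−3, 16 coarse + 24 fine epochs (the fine loss is still falling when the
coarse stage has settled, hence the longer stage-2 schedule). The end-to-end
check trains on 160 of 200 mixed-pattern phantoms and evaluates the held-out
40; the cascade-vs-coarse comparison uses 50 multiple-lesion phantoms per
seed across 5 seeds at 12 + 16 epochs. Training is deterministic on CPU for
a fixed seed (all randomness flows from one seed via spawned NumPy
`SeedSequence` streams).

## Numerical choices

- float32 weights/activations; loss and softmax accumulate in float64.
- He-normal initialisation, zero biases.
- Argmax decoding resolves ties toward the lower class index.
- Bilinear resizing uses dense per-axis interpolation matrices (rows sum to
  1, so constants are preserved); the same operator serves the input pyramid
  and the differentiable feature up-sampling.
- Max-pool gradients route to the first maximising element of each window.
- The in-package autodiff engine implements exactly the operations the
  networks need; convolution gradients reuse the same-padding convolution
  with a flipped kernel, and every operator's gradient is tested against
  central finite differences.

## Known limitations

- 2-D slices only; no 3-D context, resampling, or histogram standardisation.
- CPU NumPy training: fine at phantom scale, far too slow for 512×512
  clinical volumes at depth-4/width-64 — those defaults define the intended
  full-scale configuration rather than something this engine should train.
- No post-processing (largest-component filtering, CRFs) and no surface
  distance metrics.
- The phantom generator's realism limits (above) bound what the end-to-end
  numbers mean.
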