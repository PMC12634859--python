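# Methods

## The model

`spectracell` implements a spectral-aware convolutional network for
multi-class blood-cell image classification. Its distinguishing component is
the **learnable spectral biorthogonal downsampling unit (LSBDU)**, a drop-in
replacement for max/average pooling. For an input feature map
X ∈ R^(H×W×C), each channel c is filtered by a learnable low-pass kernel
φ_c and a learnable high-pass kernel ψ_c (both 3×3, grouped per channel,
i.e. groups = C):

    L_c = X_c ∗ φ_c        H_c = X_c ∗ ψ_c

Both bands are decimated by 2 (implemented as a single stride-2 same-padded
convolution per branch, identical to convolve-then-keep-even-indices) and
fused with per-channel sigmoid-constrained gates:

    Y_c = σ(a_c)·L̂_c + σ(b_c)·Ĥ_c,     α_c = σ(a_c), β_c = σ(b_c) ∈ (0,1)

The per-channel outputs are re-stacked into Y ∈ R^(⌈H/2⌉×⌈W/2⌉×C). The unit
is linear in its input (no bias, no nonlinearity) and adds 20 parameters
per channel (two 3×3 kernels plus two gate scalars).

**Initialization.** φ and ψ start from the two 3-tap members of the Bior2.2
biorthogonal wavelet family — the reconstruction low-pass
(√2/4, √2/2, √2/4) and the decomposition high-pass (√2/4, −√2/2, √2/4);
the longer 5/6-tap members of the family cannot fit a 3×3 support. The 2-D
kernels are separable tensor products: φ = outer(low, low) rescaled to unit
sum (DC gain 1, so constants pass the low branch unchanged) and
ψ = outer(high, high), which is zero-sum automatically since (Σh)² = 0. The
HH product is the unique symmetric zero-sum tensor product of these taps,
which is why a single high-pass kernel per channel uses it. Gates start at
a = b = 0, i.e. α = β = 0.5.

**Zero-sum constraint.** ψ must stay a genuine high-pass for the spectral
decomposition (and the attention map's constants-vanish property) to remain
meaningful, but elementwise Adam updates do not preserve the zero-sum
plane even from a zero-sum start. After every optimizer step each ψ_c is
therefore re-centered (its mean subtracted) — a retraction onto the
constraint plane. φ is left unconstrained; its DC gain is free to adapt.

**Padding.** All convolutions use "same" padding with the *edge mirror*
(the `boundary='symm'` convention). This makes spatial constancy an exact
network invariant: a constant image stays constant through every layer, the
LSBDU low branch returns it unchanged, and the high branch returns exactly
zero — which in turn makes the constant-input contracts of the attention
map exact rather than approximate at image borders. Stride-2 padding is
phased so the kept samples are the even-indexed (0-based) outputs of the
corresponding stride-1 convolution.

**Backbone.** Stem (3×3 conv → batch norm → ReLU), then stages of
depthwise separable convolution (DSC) blocks — per-channel 3×3 depthwise
filtering, BN, ReLU, then 1×1 pointwise mixing, BN, ReLU — each stage
ending in exactly one downsampling unit, then global average pooling and a
fully connected softmax head (max-subtracted, numerically stable). The
max-pool ablation swaps every LSBDU for a 2×2/stride-2 max pool and keeps
everything else identical.

A standard convolution costs DK²·M·N·DF² multiply–accumulates; the DSC
factorization costs DK²·M·DF² + M·N·DF², a reduction of exactly
1/N + 1/DK² (so it is strictly cheaper only when both N > 1 and DK > 1).

**Architecture defaults.** The published-scale profile takes 224×224×3
input: stem → 32 channels, five stages of two DSC blocks with widths
64/128/256/512/512, one downsampler each (224 → 7 before GAP). Width and
depth are fully configurable; this schedule is this package's convention,
chosen to mirror MobileNet-style doubling. The desk-scale profile
(`small_spec`) takes 64×64×3 input: stem → 16, three single-block stages of
widths 32/64/96 (64 → 8 before GAP). All experiments and tests in this
repository use the desk-scale profile.

## Training recipe

Defaults (all in `TrainConfig`): batch 32; up to 50 epochs; AdamW
(decoupled weight decay 1e-4) at initial learning rate 1e-3; cosine
annealing with warm restarts at epoch granularity, lr_min = 0, T₀ = 10,
T_mult = 2 (T₀/T_mult are common SGDR defaults — only the scheduler family
is prescribed by the training recipe this mirrors); early stopping on
validation loss with patience 5, where "improvement" means a strict
decrease by more than 1e-6, with best-weights restoration; label smoothing
ε = 0.1; focal loss α = 0.25, γ = 2.

The focal/smoothing composition smooths the target first, then applies the
focal modulation per class:

    loss = −Σ_k α · (1 − p_k)^γ · q_k · log(p_k),   q = (1−ε)·onehot + ε/K

batch-reduced by mean, with probabilities floored at 1e-12 inside the log.
This form reduces to label-smoothed cross-entropy at γ = 0, α = 1 and to
standard focal loss at ε = 0.

Data are split 80/20 (train+val/test) by per-class largest-remainder
stratified sampling; a further 10% of the training portion (stratified,
seed-controlled) is the validation carve-out — the underlying recipe states
the 80/20 split but not the validation fraction, so 10% is this package's
choice. Channel normalization statistics (per-channel mean and population
std) are computed on the training portion only. Augmentation — flips,
rotation, color jitter, random affine, cutout, in that fixed order
(geometric before cutout so holes stay axis-aligned) — is applied to the
training stream only; validation and test images are strictly
resize+normalize. Augmentation magnitudes are package conventions: flips at
p = 0.5, rotation ±20°, jitter (0.2, 0.2, 0.2, 0.05), translation ≤ 10%,
scale 0.9–1.1, shear ≤ 10°, one 32×32 cutout filled with 0. Desk-scale runs
use the `light()` profile (flips only): the synthetic cells are nearly
isotropic, and geometric/color jitter mostly slows convergence in a
15-epoch budget without adding invariances the fixture tests.

Every random source derives from one seed: data generation `seed`,
train/test split `seed+2`, weight init `seed+3`, training loop (shuffling,
validation carve-out, augmentation) `seed+4`. Two runs with the same seed
produce identical histories and metrics.

## Synthetic cell fixture

The generator emulates the *structure* of an 8-class peripheral blood-cell
dataset, not its appearance: tinted background, a jittered elliptical cell
body, a nucleus built from 1–4 overlapping disks (lobation), a
sinusoid-plus-speckle granule texture confined to the cytoplasm, and
Gaussian pixel noise (σ = 0.02), clipped to [0,1]. Class recipes place
discriminative information deliberately in both frequency bands:

- high-band-only pairs: *neutrophil-like* vs *IG-like* and
  *eosinophil-like* vs *basophil-like* differ **only** in granule
  frequency/amplitude;
- low-band-only pairs: *lymphocyte-like* vs *erythroblast-like* (cell
  radius) and *neutrophil-like* vs *monocyte-like* (radius + lobe count)
  differ **only** in geometry.

So a model that discards either band cannot separate all classes, which is
exactly the property the LSBDU's α/β fusion is meant to exploit. A 3-NN
classifier on three summary features (mean intensity, cell-area fraction,
high-frequency energy) exceeds 60% accuracy — learnable, but not trivial.

What the fixture does *not* emulate: staining variability, focus/illumina-
tion gradients, touching cells, class imbalance, or the intensity
statistics of real smears. Passing the desk-scale tests therefore shows the
pipeline learns band-split morphology cues end to end; it does not certify
performance on real microscopy data.

Default problem sizes were chosen to keep a full CPU run at desk scale: 100
images per class at 64×64 (800 images), ≤ 15 epochs. Images regenerate
bit-identically from (seed, class, index) triples.

## Evaluation panel

All metrics derive from the multiclass confusion matrix: per class
one-vs-rest TP/FP/FN/TN give precision, recall, F1 and specificity
(specificity is computed one-vs-rest from the multiclass matrix); macro-F1
is the unweighted mean of per-class F1; accuracy = trace/total;
misclassification rate = 1 − accuracy; Cohen's kappa = (p_o − p_e)/(1 −
p_e) with p_e from row/column marginals. One-vs-rest AUC uses the
Mann–Whitney U statistic with average ranks (ties count ½) — exact tie
handling, equivalent to trapezoidal ROC integration. Zero denominators
yield 0 with a logged flag, keeping report shapes stable; a class absent
from the truth yields NaN AUC.

## Interpretability

Grad-CAM: channel weights are the spatial mean of the class-logit gradient
at a chosen convolutional layer (default: the last DSC activation before
GAP); the map is the rectified weighted activation sum, bilinearly
upsampled and min–max rescaled to [0,1] (all-zero maps stay zero). The
spectral attention map is the channel mean of |β_c·Ĥ_c| at the first LSBDU
(the first unit is the default; any can be selected), rescaled the same
way — it visualizes the high-frequency band a max pool would discard. The
three-panel figure (input | spectral attention | Grad-CAM overlay at 0.5
opacity, jet colormap) is deterministic given model and image.

## Numerical choices

- Probability floor 1e-12 inside every log; early-stopping improvement
  margin 1e-6; BN ε = 1e-5, momentum 0.1 (running stats), batch statistics
  in float32.
- Attention maps whose peak is ≤ 1e-5 are reported as all-zero rather than
  min–max rescaled: such peaks are float32 roundoff (observed ≈ 1e-7 on
  constant inputs), and rescaling would amplify dust into a full-range map.
- Forward/backward in float32 activations with float64 gradient
  accumulation in AdamW moments; analytic gradients for every layer are
  verified against central finite differences at tolerance 1e-3 in the
  suite (exact to ~1e-8 in float64).
- Max pool uses ceil mode (odd sizes padded with −inf, so pads never win);
  ties in a pooling window resolve to the first (row-major) maximum.
- Stratified splitting uses largest-remainder rounding of per-class counts
  against the rounded global test total.

## Known limitations

- The engine is NumPy-based and single-threaded beyond BLAS; it is sized
  for desk-scale experiments (≈ 25 s/epoch for 720 training images at
  64×64 on one CPU), not for 224-scale dataset training.
- The LSBDU here learns analysis filters only; no synthesis (upsampling)
  bank, no multi-level pyramids, and no stain normalization are
  implemented.
- Reported desk-scale accuracies come from the bundled synthetic fixture
  and say nothing quantitative about real blood-smear datasets.
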