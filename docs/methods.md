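# Methods

## Gaze-attention map model

A fixation at screen pixel (x_c, y_c) is modeled as an isotropic Gaussian
"gaze area" G(x, y) = (1/(√(2π)σ))·exp(−((x−x_c)² + (y−y_c)²)/(2σ²)): the
tracker reports a point, but the effective field of view plus residual
calibration error make a disc of radius ~σ the honest unit of attention.
The printed constant is the one-dimensional Gaussian normalizer attached to
a two-dimensional exponent; because every map is max-normalized at the end
of the pipeline, the constant cancels and is kept only for fidelity to the
formula.

Rendering proceeds as: screen→image coordinate mapping (the image is
assumed displayed at native size centered on the screen, so image_xy =
screen_xy − (screen_dim − image_dim)/2, rounded to the nearest pixel; an
explicit offset override covers other display setups); fixations outside
the image are **dropped**, not clamped — clamping would pile spurious mass
on the borders; the surviving fixations are accumulated into an impulse
image (weight 1 each, or the fixation duration when duration weighting is
enabled — off by default); the impulse image is convolved with a separable
discrete Gaussian (default 199 taps, σ = 30 px, zero-padded borders,
reflect available); finally the map is rescaled so its maximum is 1. An
empty or fully off-image sequence yields an all-zero map with a logged
warning rather than an error, because absent gaze is a data condition, not
a programming fault. Blurring the impulse image (rather than an RGB frame)
is what makes the rendered map equal, up to one scale factor, to the exact
sum of per-fixation Gaussians — the property the oracle tests assert at
per-pixel relative error ≤ 1e-5.

σ defaults to the 30 px preset. The viewing-geometry helper
σ = (θ/360)·π·R·√((H_p·W_p)/(H·W)) converts an angular error θ (degrees) at
eye-screen distance R into display pixels via the display's mean pixel
density; with θ = 1°, R = 50 cm on a 1920×1080, 64×48 cm display it
evaluates to 11.34 px. It is exposed as a calibration aid and deliberately
not wired into the rendering default.

For the 64×64 synthetic phantoms the package uses σ = img_size/10 = 6.4 px
with a 39-tap kernel. The 30 px/199-tap preset is calibrated for
full-resolution endoscopy frames (≥500 px); at 64 px it would blur any
fixation pattern to near-uniformity and destroy the supervision signal the
generator exists to emulate. The σ:image-size ratio (~1:10) matches the
full-scale preset's regime.

## Classifier and attention consistency

The classifier contract is a bundle: feature extractor → (h, w, C) spatial
map → global average pooling → fully connected head (weights (K, C), bias
K). The network attention map is the classic CAM for the *predicted* class:
the class's head-weight vector is rectified (ReLU on weights, which
guarantees a nonnegative raw map when the extractor ends in a ReLU; the
ReLU-on-map alternative is a flag), used as channel weights over the final
feature map and summed, bilinearly upsampled (align_corners = false) to the
gaze map's resolution, and passed through a sigmoid.

The training objective is LOSS = CE + λ·MSE with CE the multiclass
cross-entropy and MSE the mean squared difference between A_model and
A_human. The MSE averages over **all** N·M pixels (standard MSE), making
the loss resolution-independent and, with both maps on [0, 1]-commensurate
scales, comparable in magnitude to CE. λ defaults to 1 (an unweighted sum);
λ = 0 is the no-gaze ablation baseline. Max-normalizing the gaze map is
what puts both operands of the MSE on the same scale as the
sigmoid-activated CAM.

Two structural consequences are worth knowing. First, with rectified
weights and nonnegative features the raw CAM is ≥ 0, so A_model ≥ 0.5
everywhere while A_human ≈ 0 off-lesion: the MSE has an irreducible floor
of roughly 0.25 × (off-lesion area fraction), and its training value should
be read relative to that floor, not to zero. Second, if every head weight
of some class becomes nonpositive, that class's CAM is identically zero
(attention constant 0.5) and the rectification blocks any gradient that
would revive it; the alignment score of such a map is reported as 0 with a
warning.

## Network stack

The extractor, CAM path, losses, bilinear resampling and Adam are
implemented directly in NumPy with analytic gradients (einsum-based
convolution, adjoint-of-interpolation upsampling backward, argmax class
selection treated as a constant). The reference backbone is three stride-2
3×3 conv + ReLU blocks, 64×64×3 → 8×8×32, He-initialized — small enough for
central-difference gradient checks, which the test suite performs on every
conv block at relative tolerance 5e-3. Production-scale backbones plug in
through the same bundle contract (forward/backward/params/grads/copy);
pretrained weights are an input, not something this package builds.

## Training protocol

Adam (lr 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with cosine-annealing warm
restarts: within a cycle of length T_i, lr = lr_min + (lr_max − lr_min)·
(1 + cos(πt/T_i))/2, T₀ = 10 epochs, cycles doubling (T_mult = 2), so
restarts fall at epochs 10, 30, 70 in a 150-epoch run. The schedule is
stepped per epoch. Batch sizes are 8 (train) and 16 (validation); no early
stopping — the loop runs all epochs and keeps the parameters of the best
validation accuracy (strict improvement). Augmentation applies one sampled
geometric transform — horizontal flip p = 0.5, vertical flip p = 0.5,
rotation uniform over {0°, 90°, 180°, 270°} — identically to the image and
its gaze map; right-angle rotations keep the gaze map free of interpolation
artifacts (free-angle rotation is intentionally not the default).
Validation is never augmented. No class weighting or oversampling is
applied by default. All randomness (shuffling, augmentation draws) flows
through one generator seeded from the config, and training is
single-threaded, so identical configs give bit-identical loss histories.
When λ > 0, every training sample must carry a gaze map; a missing map is a
configuration error naming the offending image.

## Evaluation

Metrics follow the one-vs-rest protocol: for class k, TP = cm[k,k], FP =
row-k sum − TP, FN = column-k sum − TP, TN = rest (rows of the confusion
matrix are predictions, columns truth). Accuracy, precision, recall, F1 and
the binary MCC come from those counts; Cohen's kappa = (p₀ − p_e)/(1 − p_e)
from the full matrix; AUC is the midrank (Mann–Whitney) statistic per
class. Aggregates are unweighted macro means — the per-class protocol makes
macro the natural reading, and a support-weighted alternative is a flag.
The headline MCC is the macro mean of per-class binary MCCs; the
generalized single-matrix MCC is available separately. Zero-denominator
conventions: precision/recall/F1 → 0 with a warning; MCC → 0 with a
warning; kappa with p_e = 1 is an error. Rank-based AUC (no threshold
sweep) was chosen so the implementation can be checked *exactly* against an
all-pairs counting oracle.

Attention alignment quantifies lesion localization: the attention map is
binarized at its own Otsu threshold (fixed thresholds configurable) and
compared to the ground-truth lesion mask by IoU.

## Synthetic study design

The generator targets the statistical regime the attention-consistency loss
assumes, not endoscopic realism: gaze mass concentrated on the diagnostic
region, three visually separable classes, patients owning several images.
Each 64×64 phantom has one elliptical lesion (semi-axes 13–21% of the image
side, random center/orientation) on a noisy mucosa-colored background.
Class appearance is rule-deterministic — class 0 pale and smooth, class 1
darker with a warped high-frequency stripe (vessel-like) texture, class 2
dark with an irregular near-black core — so a fixed pixel-statistics rule
(mean lesion luminance, then high-frequency energy) recovers the label; the
suite requires ≥95% recovery on 300 draws and observes ~100%. Scanpaths fix
on the lesion with probability 0.8 (Gaussian scatter, sd = 0.5 × equivalent
radius √(area/π)), otherwise uniformly over the image, at the nominal 90 Hz
tracker cadence; 20–60 fixations per image. Classes are balanced by
default; a skewed ratio (0.26/0.70/0.04) mirroring a heavy clinical
three-type imbalance is available behind a flag. Splits are assigned at the
patient level (60/20/20, floor counts with largest-remainder correction),
so no patient contributes to two splits.

What passing tests on this generator do **not** show: robustness to real
NBI texture statistics, inter-observer gaze variability, calibration drift,
multiple or absent lesions, or class boundaries that are genuinely hard —
the phantom classes are separable by construction. The synthetic results
validate the mechanics and the direction of the gaze-supervision effect,
not clinical performance.

## Study conditions for the desk-scale ablation

The shipped ablation (tests and `scripts/acceptance.py`) uses 30 patients
(7–10 images each, ≈150/50/50 images per split), 64×64 phantoms, gaze maps
at σ = 6.4/39 taps, the reference backbone, 30 epochs, and three paired
seeds. With gaze supervision (λ = 1) mean attention-lesion IoU exceeds the
λ = 0 baseline and mean test accuracy stays within 2 points — the
desk-scale analogue of the full-scale finding that gaze supervision
improves both localization and classification. The comparison is
stochastic: individual seeds can order either way; the claim is about the
paired-seed mean at these fixed conditions.

## Numerical choices and edge cases

- Coordinates are 0-based, pixel-center convention, origin top-left;
  screen→image mapping rounds to nearest integer pixel.
- Gaussian kernels are sampled (not integrated) and left unnormalized up to
  the printed constant; max-rescaling removes any kernel-sum factor.
- Bilinear resizing uses the align_corners = false convention; its backward
  pass is the exact adjoint (scatter-add of interpolation weights).
- Softmax/sigmoid/cross-entropy use max-shifted and sign-split forms for
  numerical stability.
- Tie-breaks: argmax takes the lowest index; checkpointing requires strict
  validation improvement, so the earliest best epoch wins.
- Degenerate inputs: empty fixation sequences warn and yield zero maps;
  constant attention maps get alignment 0 with a warning; empty lesion
  masks, all-zero count tables and single-class kappa are errors.

## Known limitations

- CPU-only and sized for small images/backbones; no GPU, no mixed
  precision, no data-loader parallelism (parallel loading would also break
  bit-reproducibility of the shuffle/augment stream).
- Only the FC-weight CAM is implemented — no Grad-CAM variants, no
  transformer backbones.
- The dead-CAM mode of ReLU-on-weights (all-nonpositive class weights)
  is reported, not repaired; switch to ReLU-on-map if it matters.
- Saccade/fixation event detection is out of scope: the gaze log is assumed
  already fixation-level.
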