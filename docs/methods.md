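# Methods

## Problem and supervision model

The package estimates a per-plant object count (seeds on a mature soybean
plant) from an RGB image annotated with one point per object centroid.
Supervision is purely point-level: no boxes, masks or density maps. The
model follows the point-proposal paradigm: a fixed grid of reference
points is tiled over the stride-8 feature map (K = 4 reference points per
cell, arranged in a centered 2×2 sub-pattern), and the network regresses
one offset and one confidence per reference point. The decoded prediction
set — proposals with confidence ≥ τ — is simultaneously the count and the
localization.

Coordinates are 0-based continuous pixel coordinates, origin at the
top-left, x rightward, y downward, with annotations at pixel centers.
Offsets are produced in stride units and scaled by the stride (8 px), so a
unit raw output moves a prediction by one cell.

## Architecture

Backbone → super-token attention on the deepest map → FPN fusion at
stride 8 → efficient channel attention → twin 3×3-conv heads.

* **Backbone.** `vgg19_bn` (16 convs in five blocks) and `vgg16` follow
  the standard channel plans with batch normalization after every
  convolution; `tiny` (4 convs, ≤ 64 channels, stride-2 stem) is the
  default so the suite trains on one CPU. Taps are taken at strides 8
  and 16.
* **Super-token attention.** Tokens (feature vectors per location) are
  softly associated to an h×w grid of super tokens, restricted to each
  token's 3×3 cell neighborhood; association weights are a row-stochastic
  softmax of scaled dot products, and super tokens are updated as
  association-weighted means (`assoc_iters` rounds, default 1).
  Multi-head self-attention runs among the super tokens only (quadratic
  in h·w, not in H·W), and the result is broadcast back to tokens through
  the same association weights with a residual connection. A residual
  depthwise 3×3 (convolutional position embedding) precedes the block and
  a pointwise-expand / depthwise / pointwise-project feed-forward follows
  it. Defaults: grid 8×8, 2 heads, expansion 2.
* **Channel attention.** Global average pooling gives one descriptor per
  channel; a 1-D convolution of adaptive width
  k = odd(log₂C/γ + b/γ) (γ = 2, b = 1; odd(·) truncates, then adds one
  if even, floored at 1) followed by a logistic gate rescales each
  channel. The truncate-then-odd reading matches the reference behavior
  of the adaptive-kernel rule, which is ambiguous at half-integers.
* **Fusion.** 1×1 lateral projections to `fpn_channels`, top-down
  nearest-neighbor upsample-and-add, one 3×3 smoothing conv; a single
  fused map at stride 8. The fusion parameters form their own
  learning-rate group (reduced rate), as is conventional for FPN-style
  merges grafted onto a pretrained backbone.
* **Heads.** `head_depth − 1` 3×3 conv+ReLU layers then a 3×3 projection
  to 2K (offsets) or K (logits) channels. The classification head's final
  bias is initialized to −2 so training starts from a sparse prediction
  set.

## Loss

    L_total = L_cls + λ_reg·L_reg + λ_near·L_near + λ_overlap·L_overlap

Matching is a Hungarian one-to-one assignment of predicted points to
ground truth on cost ‖p − g‖ + w·(1 − s) (w = 1 by default) — an
equivalent nonnegative form of "distance minus confidence bonus". Matched
proposals are foreground for the mean binary cross-entropy `L_cls`
(computed from logits in the stable log-sigmoid form during training) and
contribute Smooth-L1 (transition 1 px) coordinate residuals to `L_reg`.

The penalties act on the *decoded* set (confidence ≥ `score_threshold`,
default equal to τ = 0.5), not on all proposals: applied to the dense
reference grid the near penalty would saturate at d_min for every
neighboring-proposal pair and carry no useful signal. The sum in
`L_near` runs over ordered pairs (i ≠ j), consistent with its 1/N_p²
normalization — a coincident pair at d_min = 10 scores 2·10/4 = 5.
Boundary cases follow the strict inequalities (d = d_min and d = r_o
trigger nothing); N_p ≤ 1 gives L_near = 0 and N_g = 0 gives
L_overlap = 0. The exact overlap count is piecewise constant in the
coordinates, so in its default (hard) form it contributes its value but
no gradient; a soft variant (`soft_selection=True`) replaces the
indicator with sigmoid((r_o − d)/temp) and weights both penalties by
confidence products, making the whole objective differentiable through
the selection.

Default weights: λ_reg = 0.5, λ_near = λ_overlap = 0.1. The distance
scales default to d_min = r_o = 6.5 px — half the expected seed diameter
(≈ 13 px at the synthetic scale), so the penalties trigger only on
predictions closer together than one seed radius. All are configuration
fields; no claim is made that these equal any particular previously used
values, which are not public.

## Training protocol

Adam (β = 0.9/0.999), batch 4, gradient-norm clipping at 0.1, L2 weight
decay 1e-4 applied only to convolution/linear weights — parameters are
split into three groups: decayed weights, undecayed normalization scales,
and biases. The fusion group trains at `fpn_lr` (default base/10). The
schedule is a linear warm-up from base/100 to base over `warmup_epochs`
(default 3), then a half-cosine decay back to base/100; the two branches
agree at the junction. Validation runs every `eval_every` epochs
(default 2) and early stopping keeps the best-validation-MAE parameters,
halting after `patience` = 10 evaluations without an MAE improvement of
at least 1e-3.

Reference defaults follow the full-scale protocol (base_lr 1e-4,
200 epochs, 640×640 inputs are supported); the scaled-down studies in the
test suite and acceptance script use 256×256 or 128×128 scenes, 18–24
epochs and base_lr 1e-3 — a compact network trained for a few hundred
steps needs the proportionally larger rate to traverse the same loss
landscape, and the choice is recorded here as part of those studies'
configurations.

Train-time augmentations (disabled at validation/test): HSV jitter
(amplitudes 0.015/0.7/0.4), horizontal flip (p = 0.5), 2×2 mosaic
(p = 0.5), and random affine (rotation ≤ 10°, translation ≤ 10%, scale
0.9–1.1, shear ≤ 2°, p = 0.5). Every geometric transform maps the points
with the same matrix as the image; a point survives only if its
transformed center lies on the output canvas, mirroring the annotation
rule that only visibly centered objects are labeled. Mosaic scales
points with the pixel-center convention used by the resampler.

## Synthetic scenes

The generator emulates the structure of mature single-plant field images:
mottled soil background with leaf-green blobs, dark stems as downward
polylines, seeds as radially shaded beige discs clustered along the stems
(cluster spread 14 px), optional pod/stem-colored elliptical occluders.
Counts span 3–149 per image, matching the documented range of such
datasets, with density strata Sparse ≤ 37 / Medium 38–63 / Dense > 63
available as exact per-stratum targets. Ground truth is exact by
construction; a seed whose center pixel is covered by an occluder is
removed from the ground truth (the visible-center annotation rule), and
occluder geometry is drawn from per-seed random substreams so that
raising `occluder_fraction` only adds occluders — the visible count is
nonincreasing in the fraction for a fixed seed.

What the generator does **not** model: perspective and lens distortion,
specular highlights and shadows, leaf textures, seed shape variation
beyond radius/color jitter, and the long-tailed clutter of real field
scenes. Passing the end-to-end tests therefore shows that the
architecture, loss, optimization and evaluation machinery are correct and
that the counting signal is learnable through the full stack — not that
field-level accuracy transfers to real imagery.

## Numerical choices

* The network and training loop run on a small reverse-mode autodiff
  engine over NumPy arrays (float32 parameters); convolution is im2col +
  BLAS matmul, and all layer gradients are verified against central
  finite differences in the test suite.
* Pairwise distances in the differentiable penalty path use
  sqrt(x + 1e-12), so coincident points yield finite (zero) gradients;
  the analysis-path penalties are computed in float64 and match scalar
  double-loop references to ≤ 1e-9 relative error.
* Hungarian assignment uses `scipy.optimize.linear_sum_assignment`;
  rectangular costs leave the surplus side unmatched, and only the total
  cost is contractual when multiple optimal pairings exist.
* BCE probabilities are clipped at 1e-12 in the probability form; the
  training path uses the logit form and needs no clipping.
* R² on a record set with zero ground-truth count variance is reported as
  undefined (None), never clamped. RMSE confidence bounds are the square
  roots of the t-interval on squared errors, floored at zero. The
  confidence interval on R² is not reported: it is not a mean of
  per-sample values, so the t-interval does not apply.
* The conv FLOPs formula is the standard additive-bias form
  2·H·W·(C_in·K² + bias)·C_out; the parameter count is
  C_in·f²·C_out + C_out·[bias].

## Known limitations

* Hard-selection penalties pass no gradient through which proposals are
  selected, only through their coordinates; the soft variant exists but
  is off by default.
* The overlap penalty in its exact form is gradient-free; its training
  effect arrives indirectly (via the near penalty and the classification
  pressure it correlates with). This mirrors its definition as a count.
* The complexity accountant covers convolutional layers only (attention
  matmuls are excluded), and printed parameter/FLOP totals for the full
  backbone are not reproduced — the published architecture is
  under-specified at that level of detail.
* Training on one CPU limits practical input sizes; the full VGG19-BN
  configuration is functional but slow, and no pretrained weights are
  bundled.
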