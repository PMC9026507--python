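# Methods

This document records the model, the numerical choices, and the deliberate
deviations from a full-scale MRI study, so results produced with this package
can be interpreted correctly.

## Model

**Switchable generator.** One U-net translates in both directions between two
MRI-like contrasts (domain A, T1-like; domain B, T2-like). Direction is
selected by a scalar switch γ ∈ [0, 1] applied through adaptive instance
normalization (AdaIN). For a feature map x with per-channel instance mean μ(x)
and standard deviation σ(x), each AdaIN site computes

    z = σ_style · (x − μ(x)) / σ(x) + μ_style ,

with σ(x) the population standard deviation stabilized as √(var + ε), ε = 1e-5.

**Style coder.** A learned 128-dimensional embedding is passed through two
fully connected layers (leaky ReLU 0.2 between them) to produce raw (σ, μ)
vectors for all nine AdaIN sites; the σ head is rectified with ReLU so styles
are non-negative. The emitted style is the convex combination
F(γ) = (1 − γ)·(σ=1, μ=0) + γ·(σ_B, μ_B): γ = 0 is *exactly* plain instance
normalization (the A→B direction), γ = 1 applies the learned domain-B style
(the B→A direction). The output biases of the coder are initialized so the raw
σ starts at 1 and μ at 0, keeping early training close to instance
normalization for both directions.

**Architecture.** The U-net has four stride-2 4×4 encoder convolutions
(1→C→2C→4C→8C channels, leaky ReLU 0.2), four stride-2 4×4 transposed
decoder convolutions with skip concatenations after the first three up-steps,
a 3×3 fusion convolution, and a 1×1 output convolution with tanh. AdaIN is
applied after every encoder/decoder/fusion stage — nine sites with channel
widths [C, 2C, 4C, 8C, 4C, 2C, C, C, C]. Convolutions followed by AdaIN carry
no bias (AdaIN would cancel it). Default C = 64. The discriminator is a
PatchGAN: five 4×4 convolutions (strides 2,1,1,1,1; channels
1→64→128→256→512→1) with batch normalization on the middle three stages; a
128×128 input yields a 60×60 patch score map.

**Parameter economy.** At C = 64 the switchable generator plus coder has
6,742,337 parameters versus 12,658,818 for the two-generator baseline pair — a
ratio of 0.533. This is the structural basis of the efficiency claim and is
asserted (< 0.55) in the acceptance suite.

## Losses and training protocol

- LSGAN objectives: the discriminator minimizes
  ½·E[(D(real) − 1)²] + ½·E[D(fake)²]; the generator minimizes
  E[(D(fake) − 1)²].
- Cycle consistency: L1 distance of twice-translated images to their sources,
  summed over both directions, weight λ_cyc = 10.
- Identity: L1 distance of same-domain mappings to their inputs, weight
  λ_id = 5. (Adversarial weight 1.)
- Adam with β₁ = 0.5, β₂ = 0.999; learning rate 2e-4 constant for the first
  100 epochs, then linearly decayed to 0 at epoch 200; batch size 1.
- Augmentation: random 128×128 crop plus independent horizontal/vertical
  flips.
- Discriminators are updated on buffered fakes drawn from 50-image replay
  buffers (after filling, a query returns the incoming image with probability
  0.5, otherwise a random stored image is returned and replaced).
- One epoch is a pass over the smaller training domain, with independent
  per-epoch shuffles of both domains (training is unpaired).

## Evaluation

- PSNR = 20·log₁₀(MAX / RMSE) with MAX = 1 after rescaling images to [0, 1].
- SSIM with an 11×11 Gaussian window (σ = 1.5), k₁ = 0.01, k₂ = 0.03,
  population (not sample) window moments, borders cropped by half a window,
  averaged over positions. Cross-checked in the tests against both a direct
  per-window loop and scikit-image.
- Method comparisons use the two-sided Wilcoxon signed-rank test on per-image
  paired records (exact distribution for n ≤ 25 without zero differences,
  normal approximation with continuity correction otherwise), via
  `scipy.stats.wilcoxon`.

## Phantom data

Real multi-contrast MRI is not distributable with this package, so experiments
run on synthetic phantoms. Each subject slice is a randomized nested-ellipse
label map (background, fat rim, white-matter-like interior, gray-matter band
and blobs, fluid ventricle pockets) rendered twice with contrast-specific
class intensities:

| class | contrast 1 (T1-like) | contrast 2 (T2-like) |
|---|---|---|
| fat | 0.95 | 0.55 |
| white matter | 0.75 | 0.45 |
| gray matter | 0.55 | 0.65 |
| fluid | 0.15 | 0.95 |

A smooth multiplicative bias field (2–3 low-frequency cosine components,
amplitude ≤ 10%) and additive Gaussian noise (σ = 0.02) are shared-geometry
but contrast-independent. Because both contrasts are rendered from the same
label map, every pair is **registered by construction** and pixelwise metrics
are meaningful. The class means are distinct in both tables, so the
cross-contrast mapping is invertible on noiseless phantoms — the condition
under which small-scale training can be expected to beat the
input-as-prediction baseline.

**Realism limits.** The phantoms have piecewise-constant tissue, elliptical
geometry, no partial-volume effects, no anatomical variability beyond ellipse
jitter, and stationary Gaussian noise. They validate the *machinery* (losses,
switching, evaluation), not clinical image quality.

Dataset manifests are lazy: they store per-slice seeds (drawn from a spawned
`numpy.random.SeedSequence` tree, masked to 31 bits) and render images on
demand, so full-study bookkeeping (1,517 subjects × 10 slices per contrast =
30,340 slices; floor-based 70/10/20 subject split = 1063/151/303) costs
nothing to verify. Splits are at subject level, so no subject's slices leak
across train/val/test.

## Toy-scale protocol

Full-scale training (hundreds of epochs on tens of thousands of 2-D slices)
is far outside a single-CPU budget, so this package defines a documented toy
protocol used by the acceptance tests and `scripts/acceptance.py`:

- 100 subjects × 3 slices at 64×64, training subsampled to 200 slices per
  domain; subjects split 70/10/20;
- generator/discriminator base width 16, random 32×32 crops;
- 12 epochs at the full 2e-4 learning rate (the decay schedule never
  activates in a 12-epoch run); seeds fixed up front.

This runs in about 5–6 minutes on one CPU. At this scale the trained
switchable model reliably exceeds the input-as-prediction baseline in SSIM in
both directions and its cycle reconstructions are far closer to the source
than raw cross-domain comparisons, but absolute PSNR/SSIM are much lower than
full-scale results — the toy protocol validates behavior, not headline
numbers. The robustness sweep re-trains both variants at {50, 200} training
slices for 3 epochs; only execution and bookkeeping are asserted.

## Numerical choices

- All learning runs in float32 on a small reverse-mode autodiff engine written
  for this package (NumPy only). Convolutions use im2col/col2im; gradients of
  every primitive are verified against central finite differences in the test
  suite (agreement ~1e-9 in float64).
- Instance moments use the population variance with ε = 1e-5 inside the square
  root; AdaIN equivariance under input scaling is therefore exact only in the
  ε → 0 limit (relevant for very low-variance inputs).
- PSNR of identical images is reported as `inf` and excluded (with a warning)
  from summary means.
- Phantom geometry that degenerates (an empty tissue class) is retried with
  perturbed seeds, bounded at 10 attempts.

## Limitations

- No GPU path; wall-clock scaling limits experiments to toy sizes.
- Single-channel 2-D slices only; no 3-D context.
- The phantom simulator is a stand-in for real anatomy (see above).
- Batch size is fixed at 1 (instance-norm-style training), matching the
  protocol but leaving batch statistics untested.
- γ is exposed as a continuous switch and intermediate values interpolate the
  style linearly, but training only ever uses the endpoints {0, 1};
  intermediate-γ outputs are not validated against any ground truth.
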