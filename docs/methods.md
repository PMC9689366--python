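# Methods

## Problem setting and data model

A *growth annotation* is one radiologist's view of one nodule across
two CT studies: a 32×32 nodule-centred axial patch and binary mask at
baseline (T0) and follow-up (T1), the longest axial diameters D0 and D1
in mm, the elapsed time in days and the pixel spacing in mm/pixel.
Growth is defined by the radiological guideline criterion
D1 − D0 > 2 mm (strict). A cohort holds 1–3 annotations per nodule;
splits are performed at the nodule level so no nodule contributes to
both training and test sets.

Patches are stored as 16-bit greyscale PNG with intensities normalized
to [0,1]; the CT windowing behind that normalization is deliberately
unspecified — any fixed monotone mapping works, and the synthetic
generator produces patches already in [0,1]. Masks are {0,1} with
0-based row/column coordinates and the nodule centroid at the patch
centre.

Conditioning scalars: the time to predict is binned at 183/365/730 days
(calendar half-year, year, two years) into the ordinal guideline
categories (≤6, 6–12, 12–24, >24 months), mapped to {0, ⅓, ⅔, 1}; the
baseline diameter is clamped at 30 mm — the conventional nodule/mass
boundary — and scaled to [0,1].

## Network

Both subnets are 2D U-ResNets sharing one architecture; the posterior
differs from the prior only by the extra input channel for I1. The
encoder has four resolution levels (32→16→8→4) with residual blocks of
two 3×3 convolutions and channel widths f/2f/4f/8f (f = `base_filters`,
default 32); the two conditioning scalars are tiled to 4×4 and
concatenated with the encoder output, after which two further pooled
residual stages reach 2×2 and 1×1 (downsampling is 2×2 average pooling
throughout). The decoder mirrors the ladder upward with
skip connections from every encoder scale.

Four latent blocks sit in the decoder at spatial scales 1, 2, 4 and 8 —
one-channel Gaussian grids, i.e. flattened latent dimensions 1, 4, 16
and 64. Each block predicts a mean and a raw-scale channel with a 1×1
convolution; the standard deviation is `softplus(raw) + 1e-5` for
positivity and KL stability. The sampled grid is concatenated back into
the decoder features before the next block, so finer latent
distributions are conditioned on the coarser draws in both subnets.
The latent heads are initialized with near-zero weights so prior and
posterior start from matching N(0, softplus(0)) latents and the KL term
starts near zero rather than dominating early training.

Attention gates (additive gating: `α = σ(ψ(relu(W_g·g + W_x·x)))` with
1×1 convolutions and an internal width of half the skip channels)
multiply each skip connection before concatenation; `use_attention=False`
replaces them with the identity. `use_d0_input=False` drops the
diameter channel. Together with the reconstruction-mode switch these
toggles reproduce the ablation variants (BCE vs IoU loss, with/without
the diameter L1 term, attention, D0 input).

During training the prior decoder is run with the posterior's sampled
latents injected at every level (reparameterized, so gradients reach
the posterior parameters); the KL between the two hierarchies is the
closed-form diagonal-Gaussian expression summed over levels and cells,
estimated with the single latent draw per step that also drives the
reconstruction — the standard single-sample estimate for hierarchical
conditional VAEs, since the nested expectation has no closed form.

## Loss

`L_rec = L_IoU + γ·|D1′ − D1|` with γ = 1/8 by default; the total loss
adds β = 1 times the hierarchical KL. The soft IoU loss is
`1 − (Σpy + ε)/(Σp + Σy − Σpy + ε)` with ε = 1e-6, averaged over the
batch. Alternative modes: `iou_only` (drops the diameter term) and
`bce` (plain per-pixel cross-entropy; no online negative mining).

The diameter of a soft mask must be differentiable to carry the L1
term. We use a smooth caliper: pixel-centre coordinates are projected
onto 24 directions θ ∈ [0, π); per direction the soft extent is the
difference between softmax- and softmin-weighted mean projections with
weights `mask · exp(±T·projection)` (temperature T = 4 px⁻¹ in
training); the diameter is the largest directional extent plus a
mass-gated pixel extent (`Σw/(Σw+0.1)`, so an empty mask measures ≈ 0
while any real mask gains the +1-pixel extent convention), times the
spacing. The exponents are shifted per sample to the mask's own support
to avoid overflow; those exponential factors are constants of the
graph, so gradients flow through the mask values. On binary masks the
soft measure agrees with the hard extractor within 0.5 px at T = 8
(verified over 100 random phantoms). A configuration fallback
(`diameter_mode="hard"`) instead measures the 0.5-thresholded mask with
the exact extractor, in which case the diameter term is a constant of
the graph and gradients flow only through the IoU term.

Hyperparameter defaults follow the published configuration: Adam,
learning rate 1e-4, batch size 8, 200 epochs, γ = 1/8, β = 1. Data
augmentation applies one random rotation (±15°) and integer translation
(±3 px) per record per step, identically to both images and the target
mask (bilinear for images, nearest-neighbour for masks); the ranges are
our choice, the transform types are the published ones. Training aborts
with a diagnostic on a non-finite loss.

## Monte-Carlo post-processing

K prior-subnet samples (default 1000) are thresholded at 0.5 (our
choice; the binarization rule is otherwise unspecified), reduced to the
largest 4-connected component (a nodule is a single lesion), and
measured with the hard Feret extractor: maximum pairwise distance
between foreground pixel centres plus one pixel extent, times the
spacing — calibrated so a rasterized disk returns its nominal diameter
and a single pixel measures one pixel spacing. Growth sizes
Δₖ = D1ₖ′ − D0 yield Δ̄ and s_Δ (population 1/K std, stated for
bit-reproducibility), the logistic growth probabilities
Fₖ = 1/(1+e^{−(Δₖ−2)}) yield F̄ and s_F (F̄ is the mean of per-sample
probabilities, not the logistic of Δ̄), and per-pixel mean/std images
of the *soft* samples summarise the expected appearance. The binary
growth call is F̄ > 0.5 (strict). If every sample is empty, Δₖ = −D0
and the estimate is flagged (`all_empty`).

## Evaluation

Point-estimate metrics: balanced accuracy, precision and recall of the
growth call (empty denominators reported as NaN), growth-size MAE in
mm, and Dice between the thresholded mean image and the reference mask
(both-empty masks score 1 by convention). Distribution metrics:

- **Generalized energy distance** with d = 1 − IoU (d = 0 for two empty
  masks): `GED² = 2·E[d(Y′,Y)] − E[d(Y′,Y′)] − E[d(Y,Y)]`, clipped at 0
  before the square root. Two aggregations are reported and labelled,
  since the choice is ambiguous: *pooled* (components averaged over
  cases first, then combined) and *per-case* (GED per case, then
  averaged).
- **Balanced accuracy at 2 standard deviations**: the interval
  Δ̄ ± 2s_Δ replaces the point estimate; a positive needs the interval's
  lower bound above 2 mm, a negative needs its upper bound at or below
  2 mm. This is never easier than the point-estimate call.

Closest-annotator selection uses the 1-D Mahalanobis distance
|g_rx − Δ̄|/s_Δ for growth (interpreting "distance to the predicted
growth vector" as distance to its summary (Δ̄, s_Δ); absolute
difference when s_Δ = 0; ties to the lowest index) and the highest mean
Dice against the sample set for segmentation. The stratified report
bins cases by growth size (≤0, (0,2], (2,5], >5 mm — the bin edges are
our choice) and time to predict (the four guideline bins) and also
reports the aggregate accuracy excluding the >24-month bin.

## Synthetic cohort

The generator emulates the statistics of a longitudinal clinical cohort
rather than its images:

- **Shape**: star-convex phantoms, radius(θ) = R·(1 + irregularity ·
  smooth periodic noise), rasterized and rescaled iteratively against
  the hard Feret extractor so the mask's measured diameter lands within
  one pixel spacing of the target. Default irregularity 0.25.
- **Growth**: g ~ N(growth_mean·(0.5 + t_norm), growth_std) with
  defaults 2.6 ± 3.8 mm, so expected growth increases with the time to
  predict while the cohort-level mean stays at `growth_mean` (follow-up
  bins are sampled uniformly, then a day within the bin). The follow-up
  diameter is floored at 0.
- **Annotators**: up to three readers, each adding N(0, 0.97 mm) noise
  to both diameters (floored at 0.5 mm). This reproduces the published
  inter-observer statistics: pooled pairwise standard deviation
  ≈ 0.97 mm and mean absolute pairwise difference of growth readings
  ≈ 1.55 mm. Readers drop out independently with probability 0.15
  (annotator 0 retained if all would drop), matching unequal
  per-reader counts: 122 nodules yield ≈ 313 annotations.
- **Images**: the mask is blurred (Gaussian, σ = 1 px) and overlaid
  with mild background noise. The baseline image's interior intensity
  is shifted in proportion to the nodule's subsequent growth
  (`growth_signal`, default 0.35). This cue is what makes the
  prediction task learnable at all: the real predictive signal in CT
  texture is unknown, so this is a test-harness convention, not a
  biological claim. Masks are rendered per annotator from that
  annotator's diameters with the nodule's shape noise, giving realistic
  reference-mask variability.
- **Spacing**: default 0.75 mm/px; when a nodule would not fit the
  32×32 patch at that spacing (diameters up to 25 mm at baseline), the
  record's spacing is enlarged just enough that the larger time point
  spans at most 90% of the patch — the per-record spacing field exists
  precisely so downstream measurements stay in mm.

What passing tests on this cohort do **not** show: robustness to real
CT texture, attachment to pleura or vessels, part-solid morphology,
scanner or dose effects, or any clinically validated predictive signal.
They do show that the architecture, loss, sampling and metrics are
internally consistent and can extract a growth signal when one exists.

## Numerical and engineering choices

The network runs on a minimal reverse-mode automatic-differentiation
core written on numpy (`nodugrowth._autodiff`): tensors with a recorded
graph, im2col convolutions, 2×2 average pooling, nearest-neighbour
upsampling, the elementwise ops the model needs, and Adam. Gradients of
every op are validated against finite differences in the test suite.
Weights use He fan-in initialization from a generator seeded by the
network config; all randomness (simulation, initialization, training
shuffles and augmentation, Monte-Carlo sampling) flows from explicit
seeds, and the CLI fans a single global seed into named substreams, so
manifests, loss histories and prediction tables reproduce bitwise
(floating-point fields rounded to 6 decimals in CSV output).

Problem sizes in the test suite are scaled to a desk run: the
end-to-end learnability check trains a `base_filters=8` model for 25
epochs at learning rate 1e-3 on ≈ 200 synthetic annotations (80
nodules) and evaluates with K = 100 samples per held-out record —
about three minutes on one CPU — while the package defaults remain the
published configuration (f = 32, 200 epochs, lr 1e-4, K = 1000). The
higher learning rate compensates for the short schedule; the loss falls
by well over 30% and the held-out balanced accuracy of the growth call
reaches ≈ 0.72 under these conditions.

## Known limitations

- 2D axial patches only; tumour growth is a 3D process and no 3D
  extension is provided.
- Aleatoric uncertainty only: Monte-Carlo sampling over the latent
  hierarchy captures annotation/image ambiguity, not parameter
  (epistemic) uncertainty.
- The KL uses a single-sample estimate; with β = 1 the posterior can
  collapse toward the prior on easy synthetic cohorts, narrowing sample
  diversity (s_Δ small but nonzero).
- No DICOM ingestion, nodule detection or centring: inputs are already
  extracted, centred patches.
- The comparison baselines (deterministic U-Net, probabilistic U-Net,
  Bayesian test-time dropout, Pix2Pix) are out of scope.
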