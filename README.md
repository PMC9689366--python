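# nodugrowth

Probabilistic prediction of future lung-nodule growth from a single
baseline CT patch.

## The problem

Radiologists assess lung-nodule progression by comparing the longest
axial diameter across follow-up CT studies: an increase of more than
2 mm is the guideline criterion for growth and a strong malignancy
signal. Predicting that change *before* the follow-up scan — from the
baseline image alone — would support earlier, personalised management.
Two sources of uncertainty make a single deterministic answer
misleading: intrinsic image noise, and inter-observer variability
(different radiologists routinely disagree by 1–2 mm on the same
nodule). This package treats the future segmentation as a distribution
to be sampled, not a point to be regressed.

## The model

The core is a hierarchical probabilistic U-ResNet with two structurally
identical encoder–decoder subnets:

- the **prior** subnet sees the 32×32 baseline patch `I0` plus two
  scalars tiled onto its encoder output: the normalized time-to-predict
  `Tdiff` (ordinal follow-up bins ≤6 / 6–12 / 12–24 / >24 months mapped
  to {0, ⅓, ⅔, 1}) and the normalized baseline diameter `D0`;
- the **posterior** subnet additionally receives the follow-up patch
  `I1` and defines the variational distribution.

Four latent blocks of dimensions 1, 4, 16 and 64 (one-channel grids of
1², 2², 4², 8²) are interleaved coarse-to-fine in the decoder; each
emits a diagonal Gaussian, and the sampled grid is concatenated back
into the decoder so finer latents are conditioned on coarser draws.
Attention gates weight every skip connection before concatenation.
Training minimises

```
L_ELBO = L_IoU(Y, Y′) + γ·|D1 − D1′| + β·Σᵢ KL(q(zᵢ|z<ᵢ, I0, I1, Tdiff, D0) ‖ p(zᵢ|z<ᵢ, I0, Tdiff, D0))
```

with the prior decoder driven by the posterior's latent samples
(γ = 1/8, β = 1, Adam, lr 1e-4, batch 8 by default). The diameter term
uses a differentiable soft-Feret caliper so the predicted longest
diameter `D1′` (in mm) carries gradient.

At inference the prior subnet is sampled K times (default K = 1000);
each thresholded sample is reduced to its largest connected component
and measured, giving K growth sizes `Δₖ = D1ₖ′ − D0`. The package then
reports the growth size `Δ̄ ± s_Δ`, the growth probability
`F̄ ± s_F` with `Fₖ = 1/(1 + e^{−(Δₖ − 2)})` (0.5 exactly at the 2 mm
threshold), and per-pixel mean/std images of the sampled future
appearance.

Because clinical follow-up cohorts with multi-reader annotations are
not public, the package ships a synthetic-cohort generator that
emulates one: star-convex nodule phantoms at two time points, growth
≈ 2.6 ± 3.8 mm, follow-up intervals of 32–2464 days, up to three
annotators with 0.97 mm diameter noise and per-reader dropout, and a
deliberately learnable appearance cue linking baseline texture
intensity to subsequent growth.

## Worked example

```python
import nodugrowth as ng
from nodugrowth.hpnet import NetworkConfig
from nodugrowth.objective import TrainingConfig, train

cohort = ng.generate_cohort(ng.SimulationParams(n_nodules=80, seed=11))
train_set, test_set = ng.split_by_nodule(cohort, train_fraction=0.7, seed=11)

model, history = train(
    train_set,
    NetworkConfig(base_filters=8, seed=11),
    TrainingConfig(epochs=25, learning_rate=1e-3, seed=11),
)

rec = test_set.records[0]
t_norm, d_norm = rec.conditioning()
est = ng.monte_carlo_predict(
    model, rec.image_t0, t_norm, d_norm, rec.d0_mm, rec.spacing_mm,
    K=100, seed=7,
)
print(f"predicted growth: {est.delta_mean:.1f} +/- {est.delta_std:.1f} mm")
print(f"growth probability: {est.prob_mean:.2f} +/- {est.prob_std:.2f}")
print(f"growth call: {ng.classify_growth(est)}")
```

prints (about four minutes on one CPU):

```
predicted growth: 6.1 +/- 0.1 mm
growth probability: 0.98 +/- 0.00
growth call: 1
```

The model predicts that this 7.3 mm nodule, asked about a follow-up
1596 days ahead, will have grown by 6.1 mm (the annotated growth was
8.8 mm) with a 98% probability of exceeding the 2 mm guideline
threshold, so the binary growth call is positive. The ELBO on this run
falls from 2.60 to 0.41 over 25 epochs, and the 2 mm growth call on the
held-out split reaches a balanced accuracy of about 0.72 with K = 100
samples per nodule.

The same pipeline is available from the shell:

```sh
nodugrowth simulate --config cfg.yaml --out sim --seed 5
nodugrowth train    --config cfg.yaml --manifest sim/cohort/manifest.csv --out model --seed 5
nodugrowth predict  --checkpoint model/checkpoint.npz --manifest sim/cohort/manifest.csv --out pred --K 1000 --seed 5
nodugrowth evaluate --checkpoint model/checkpoint.npz --manifest sim/cohort/manifest.csv --out eval --criterion closest --seed 5
```

Evaluation reports balanced accuracy / precision / recall of the growth
call, growth-size MAE (mm), Dice of the mean predicted segmentation,
the generalized energy distance between sample and reference mask sets
(d = 1 − IoU), and the balanced accuracy of the ±2 standard-deviation
growth interval, optionally against per-annotator, averaged, or
closest-annotator ground truth.

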