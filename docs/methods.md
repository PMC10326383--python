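# Methods

## Model

The package treats a subject's brain as an R-region weighted network
per imaging modality. Functional networks are Pearson-correlation
matrices of regional time series (unit diagonal, entries in [−1, 1]);
structural networks are streamline-count matrices divided by total
brain volume (non-negative, zero diagonal — self-connections are
undefined for tractography). Modalities are stacked into an R × R × n
tensor per subject, the unit of training. The classification target is
binary: abnormal (AB = 1, the positive class everywhere in the package)
vs. healthy control (HC = 0).

Three convolutional networks are declared as layer tables and compiled
onto an in-package autodiff engine:

* a generator of seven transposed convolutions mapping a latent vector
  of 100·n values (presented as a 1×1 spatial map with 100·n channels —
  the only reading of the tabulated "1 × 100 × n" input consistent with
  the first layer producing 4×4×512 under kernel 4, stride 1, padding
  0) to an R × R × n matrix in [0, 1] via a final Sigmoid;
* a critic of six convolutions ending in an unbounded 5 × 5 × n patch
  map (patch-based discrimination: local realness scores instead of one
  scalar). The scalar used in the losses is the *mean* of the patch
  map, chosen over the sum because it is invariant to the patch count;
* a classifier with the critic's trunk and a final 2 × 2 × 1 map whose
  mean is the class logit (binary cross-entropy with logits; predicted
  class is logit > 0). The tabulated channel progression 16 → 64 → 128
  is used verbatim for both critic and classifier.

Batch normalization is applied on all layers except each network's
first and last. Because batch statistics couple the samples of a
batch — which interferes with the per-sample input gradients in the
gradient penalty — the critic's normalization can be switched to
instance normalization or disabled; the default remains batch
normalization for fidelity to the architecture tables.

Training minimizes the Wasserstein-with-gradient-penalty critic loss
L_D = E[D(x̃)] − E[D(x)] + λ·E[(‖∇x̂D(x̂)‖₂ − 1)²] with interpolates
x̂ = ε·x + (1 − ε)·x̃, ε ~ U(0, 1) per sample, and the companion
generator loss L_G = −E[D(x̃)]. Conditioning appends a one-hot class
label to the generator latent and one constant label channel to the
critic input; with conditioning off the channel counts reduce exactly
to the tables.

## Multiple-loop learning

The training pool is managed as three disjoint sets — database,
carryover, selected — whose union is always the full training set. Per
loop:

1. the batch is filled to a fixed per-class size (x = y enforced) by
   moving carryover in and drawing the remainder uniformly from the
   database;
2. class-conditioned fakes are generated from fresh noise;
3. each real sample is scored by the Euclidean distance between its
   flattened critic patch map and the centroid of the fake patch maps
   of its class; rankings ascend within class, ties broken by sample id;
4. the top half (per class, ceiling rule: ranks 1..⌈m/2⌉) trains the
   classifier; ranks ⌈m/2⌉+1..⌈3m/4⌉ carry over; the bottom quarter
   returns to the database;
5. trained-on samples also return to the database and may be redrawn.

The loop stops when validation accuracy has not improved by more than
1e-3 for 3 consecutive loops (both configurable), or when the loop
budget is exhausted — in which case the result carries a warning flag
rather than raising.

Design choices the published procedure leaves open, decided here:

* **Ranking direction.** "Top-ranked" = smallest critic-space distance,
  operationalizing "easier-to-learn" as proximity to the generator's
  learned distribution; a flag flips the direction for ablation.
* **Distance reference.** The per-class *centroid* of fake patch maps,
  not pairwise minima: deterministic, O(batch) instead of O(batch²),
  and nothing in the procedure prescribes a pairing.
* **Pool routing.** Only the bottom quarter is explicitly routed back;
  we also return trained-on samples (so random selection draws from a
  replenished pool), re-rank carryover together with fresh draws, and
  regenerate fakes each loop from fresh noise.
* **Generator/critic freezing.** Both are frozen after pre-training by
  default; `refresh_gan` optionally applies extra adversarial updates
  each loop.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| λ (gradient penalty) | 10 | weight of the Lipschitz penalty; the standard WGAN-GP value |
| optimizer | Adam, lr 1e-4, β = (0.5, 0.9) | WGAN-GP defaults |
| critic steps per generator step | 5 | WGAN-GP default |
| LeakyReLU slope | 0.2 | community default for critic/classifier |
| batch_per_class | 8 | per-loop batch; must be ≥ 4 so ranking quarters are non-empty |
| patience / min_delta | 3 / 1e-3 | convergence rule on validation accuracy |
| split fraction / mode | 0.8 / matrix_level | matrix-level mirrors the original 80/20 pool over enhanced matrices; subject_level is offered because matrix-level lets augmented copies of one subject straddle the split — a leakage risk surfaced, not hidden |

Min–max scaling is applied per subject and per channel (never across
the dataset), so no statistic crosses the train/test boundary and
scaled inputs match the generator's [0, 1] output range. Negative
functional correlations are passed through to scaling without
thresholding. Augmentation follows scaling; the shift permutes entries
without changing values, so the order only fixes reproducibility.

## Synthetic data

The generator emulates a balanced case/control cohort: one base
connectome shared by all subjects, a class mean-shift of
effect_size · noise_sd on a random fraction (`effect_edges`) of edges —
so `effect_size` is the standardized mean difference per affected
edge — and independent symmetric Gaussian noise. Each modality draws
its own effect mask, giving channels complementary signal. The shared
base makes within-class variability pure noise, the simplest setting in
which "easier-to-learn" samples are well defined for ranking tests.
Defaults are the desk-scale geometry (R = 40, 40 + 40 subjects, two
modalities, effect_edges 0.1, effect_size 1.0, noise_sd 0.5);
`paper_geometry()` switches to R = 164 with 42 + 42 subjects, matching
the original cohort's counts. A latent-factor model with per-class
loadings generates regional time series for testing the functional-
network path; its population correlation matrix is available exactly
for comparison against empirical correlations.

What the synthetic model deliberately lacks: spatial community
structure, subject-level covariates (age/sex), scanner or site effects,
heavy-tailed edge distributions, and any coupling between the
functional and structural channels beyond sharing the class label.
Passing tests therefore establish the *mechanics* (shapes, losses,
bookkeeping, convergence on separable data), not clinical performance;
the full-cohort ADNI accuracy/AUC figures are out of scope.

## Numerical choices

* All arithmetic in float64 on an in-package reverse-mode autodiff
  engine; backward passes construct differentiable graph nodes, so the
  gradient penalty's parameter gradients (derivatives of an input-
  gradient norm) are exact, verified against finite differences.
* Pearson correlations are clamped to [−1, 1] and the diagonal set to
  exactly 1 to absorb rounding; population vs. sample normalization
  cancels in the ratio. Zero-variance regions are a named error, never
  a silent 0/NaN.
* Gradient norms add 1e-12 under the square root to keep the penalty
  differentiable at zero gradient.
* Region ordering is taken from input files and must match across a
  subject's modalities; nothing is re-sorted.
* Split sizes use floor(fraction · total) for the training side, with
  a seeded shuffle; ranking ties break by sample id; partition counts
  use ceilings (⌈m/2⌉, ⌈3m/4⌉) so set sizes are reproducible for any m.
* One global seed fans out to named substreams (data, init, split,
  loop-draws, classifier-init), so every component is independently
  reproducible and a resolved-config sidecar replays a run
  byte-for-byte on the same platform.

## Desk-scale experiments

The full 164-region architecture is instantiated and shape-verified in
the tests, but training experiments run at a reduced geometry — any
spatial size 5·2^m (40 by default) with a channel-width factor
(0.25 in the tests) — which is *not* the published architecture and is
labeled as such. End-to-end runs use R = 40, 40 + 40 subjects, 2
epochs of GAN pre-training and up to 10 loops; on separable data
(effect_size 2.0) held-out accuracy reaches ≥ 0.9 within 10 loops, and
with effect_size 0 it stays inside the binomial 95 % band around
chance.

One observed limitation: at this scale the critic's Wasserstein
estimate (recoverable from the logged L_D and penalty values) grows
during the short pre-training budget — the critic improves faster than
the small generator closes the gap, which is common early WGAN-GP
behavior. The approach of the two distributions is therefore a
monitored quantity in the training curves, not an asserted test
property. Likewise the loop-to-loop accuracy trend is logged in
`history.csv` rather than asserted, since per-loop accuracy on small
validation sets is noisy.

## Known limitations

* No GPU path, no mixed precision; the NumPy engine is adequate for the
  reduced geometry and for full-size forward passes, but full-size
  adversarial training at cohort scale is outside desk budgets.
* Binary classification only; the pool bookkeeping assumes exactly two
  balanced classes.
* The critic's batch-norm default is faithful to the architecture
  tables but theoretically at odds with per-sample gradient penalties;
  use `critic_norm: instance` when that matters.
* Whether augmented originals belong in the 80/20 pool is not specified
  upstream; originals are kept as separate records flagged
  `is_original` so either convention can be filtered.
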