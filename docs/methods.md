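# Methods

`lcanet` studies how the *population nonlinearity* of a lateral-inhibition
sparse-coding network shapes three observable properties of its model
neurons — the geometry of their iso-response surfaces, their stimulus
selectivity, and their resistance to adversarial perturbation — and
contrasts each against pointwise-nonlinearity controls that share the same
feedforward weights. Everything runs on synthetic stimuli generated by the
package itself.

## The encoder model

Stimuli are image patches flattened to vectors `s ∈ R^P`. The generative
assumption is a sparse linear model `s = Φ a + ε` with a `P × N` dictionary
`Φ` (unit-norm columns), nonnegative sparse coefficients `a`, and Gaussian
pixel noise `ε`. Encoding inverts this model by minimizing

    E(a) = 1/2 ‖s − Φ a‖² + λ Σᵢ |aᵢ|,   a ≥ 0,

via the locally competitive algorithm (LCA): membrane potentials `u` obey

    u̇ = (1/τ)(b − G̃ a − u),   a = T_λ(u),

where `b = Φᵀ s` is the feedforward drive, `G̃ = ΦᵀΦ` with the diagonal
(self-connection) removed is the lateral-inhibition matrix, and `T_λ` is
the nonnegative soft threshold (`0` for `u ≤ λ`, `u − λ` above). Inhibition
between two neurons is therefore exactly their receptive-field overlap.
Integration is forward Euler with a single dimensionless step `dt/τ`.

Defaults: `λ = 0.2` (stimuli are standardized to zero mean, unit L2 norm
before encoding, so λ is on the scale of a unit-norm projection),
`dt/τ = 0.05`, `T = 150` steps. These are standard LCA practice; the
fixed-point residual `‖u − (b − G̃a)‖∞` is measured in the tests rather
than assumed (it shrinks roughly exponentially in `T`; convergence-critical
checks such as the nonnegative-lasso equivalence use `T = 4000`,
`dt/τ = 0.1`). Energy descent along the dynamics is verified empirically
(non-increasing after the first step within 1e-8 on random instances); it
is a property of the continuous dynamics that survives this step size but
would fail for `dt/τ` near 1.

Dictionary learning follows the energy gradient with respect to `Φ`:
`ΔΦₖ = η (s − ŝ) aₖ` averaged over minibatches (default 100), with every
column renormalized to unit norm after each update — without
renormalization the norms drift and `G̃` loses its interpretation as
receptive-field overlap. Training diverging (epoch-mean energy rising more
than 10% epoch-over-epoch) raises a failure carrying the training log.

The pointwise controls — linear `Φᵀs`, rectified `max(0, Φᵀs + β)`, and
sigmoidal `σ(g(Φᵀs + β))` — reuse the LCA dictionary verbatim (the
identical-weights design), so any difference in behavior is attributable to
the population nonlinearity alone. All gradients through the LCA encoder
are exact reverse-mode derivatives of the unrolled `T`-step computation
with threshold subgradient `1{u > λ}` (zero exactly at `u = λ`), so the
"attacker" differentiates precisely the function the encoder evaluates.

## What the synthetic generators emulate

* **Sparse patches** realize the generative model itself: a ground-truth
  bank of random Gabor atoms (orientation uniform on [0, π), phase on
  [0, 2π), frequency 0.08–0.35 cycles/px, envelope width 12–30% of the
  patch, positional jitter ±30%), coefficients independently active with
  probability 0.05 and Exponential(1) magnitudes (nonnegative,
  heavy-tailed, matching the nonnegative code and the l1 prior), pixel
  noise sd 0.02. Patches are standardized before encoding, mirroring
  whitened-patch training regimes. This emulates the *statistics* the model
  assumes, not natural images: real patches have 1/f structure, occlusions
  and correlations between atom activations that the generator omits, so
  passing tests show the analysis machinery behaves as theory predicts on
  model-matched data, not that the conclusions transfer verbatim to any
  natural-scene corpus.
* **Grating batteries** are full-field sinusoids
  `contrast · sin(2πf(x cosθ + y sinθ) + φ)` on the centered pixel lattice
  (x rightward, y downward in row-major order, orientation CCW from
  horizontal). Default battery: 32 orientations × 8 phases × 3 frequencies
  at unit contrast.
* **Toy classes** are fixed prototypes of 2–4 soft oriented bars at
  class-specific poses, sampled with Gaussian positional jitter (sd 0.5 px)
  and pixel noise (sd 0.05), clipped to [0, 1]. The defaults make the task
  easy but not trivial (a nearest-prototype classifier scores >90%), which
  is what the attack comparison needs: both classifier families must reach
  matched, high accuracy so that perturbation size — not accuracy — is the
  measured variable.

All generators are pure functions of their arguments including the seed.

## Response-plane protocol

A neuron `k` is probed on 2-D stimulus planes spanned by its normalized
weight vector `Φ̂ₖ` and an orthonormal second axis `ν`, obtained either by
one Gram–Schmidt step from another neuron's weight ("comparison" planes —
the choice that maximizes the chance of lateral competition) or as a random
direction in the orthogonal complement ("random" planes). Responses are
sampled on a 30 × 30 grid spanning [−2, 2]² (900 presentations per plane;
2.0 is a compromise radius for unit-norm stimuli — far enough to cross the
half-maximum contour for every encoder, near enough that grid resolution
is not the bottleneck), normalized by the grid maximum and cut into 10
bins.

Iso-response contours are extracted by marching squares at a level of 0.5
of the normalized response, keeping the connected component nearest the
positive `Φ̂ₖ` half-axis. Curvature is the quadratic coefficient of the
least-squares fit `x(y) = c₂y² + c₁y + c₀`: `c₂ > 0` means the contour
bends away from the origin (exo-origin — the hyperselectivity signature),
`c₂ < 0` toward it. The response-attenuation curvature is `−d₂` from the
fit `r(y) = d₂y² + d₁y + d₀` of the normalized response along the grid
column at the on-axis half-maximum crossing (the smallest positive
crossing; if an encoder's half-maximum sits exactly at the origin, as for
the unbiased sigmoid, the crossing nearest the axis is used). Planes where
the level is never attained, or where fewer than 5 contour points span a
nonzero y-range, are flagged and carried as failed rows rather than
dropped.

A caveat found while validating this protocol: with Gabor-like
dictionaries, whose pairwise overlaps concentrate near zero, a randomly
chosen comparison neuron usually cannot inhibit the target at all, whereas
a random orthogonal direction distributes drive over many mildly
overlapping atoms whose summed inhibition grows with displacement. At
these scales the *bulk* of random-plane curvature therefore exceeds the
bulk of comparison-plane curvature, and only the comparison-plane *tail*
(high-overlap pairs) is heavier. The exo-origin prevalence itself (the
large majority of comparison-plane contours bending outward) is robust.

## Selectivity measures

Orientation tuning is the envelope response — the maximum activation over
phases and frequencies at each orientation (max rather than mean because
these are phase-sensitive units; the envelope is what the standard
circular-variance convention expects). Circular variance uses the
doubled-angle resultant `CV = 1 − |Σ rⱼ e^{2iθⱼ}| / Σ rⱼ`, so `CV = 0` is
perfectly orientation-locked and `CV = 1` untuned. All-zero tuning curves
are excluded as undefined.

"Selected images" of a neuron are the members of a probe set (default
20,000 generative-model patches; 100,000 reachable by config) whose
activation reaches at least 50% of the neuron's maximum over the set,
together with the angles between those images and the neuron's weight
vector. Reported comparisons are always paired per-neuron between the LCA
encoder and an identical-weights pointwise control, summarized by
median/quartiles/5–95 percentiles. The overcompleteness sweep (1×, 2×, 4×)
uses matched Gabor banks of 64/128/256 atoms over 64 pixels with a common
probe set.

## Attacks and the robustness comparison

Single-neuron attacks iterate projected sign-bounded gradient steps
`q = η ∇fₖ(s+e) + e`, `e ← sgn(q) ⊙ min(|q|, ε)`, so every perturbation
satisfies `‖e‖∞ ≤ ε` exactly. Because the gradient is everywhere
orthogonal to the neuron's iso-response contours, attack trajectories are
predicted by the response geometry: straight along `Φₖ` for pointwise
encoders, bending toward the weight vector for the population-nonlinear
encoder. The tests verify this against contour tangents traced
independently from the response grid.

Classifier attacks are targeted and confidence-halted: iterate
`s* ← clip(s* + α sign(∇ log p(y_target | s*)))` with a uniformly random
incorrect target label, pixel clipping to [0, 1], and no norm bound; the
halting iterate is the first with target confidence ≥ 0.90, and a second
snapshot is stored at 0.95 for visualization (the attack therefore runs to
the snapshot confidence; perturbation MSE — mean squared pixel change — is
measured at the halting iterate). Non-halting attacks within the iteration
budget (α = 0.01, 2000 iterations at desk scale) are flagged and excluded
from MSE summaries, with counts reported.

The comparison pairs a softmax read-out of a (fixed, unsupervised-trained)
LCA code against a one-hidden-layer leaky-rectifier network on raw pixels
with the hidden width chosen to match total trainable-weight count. Both
are trained by deterministic full-batch quasi-Newton minimization of the
cross-entropy **with a small identical ridge penalty (1e-3)** on the weight
matrices. The ridge matters: the toy classes are linearly separable, so
unpenalized cross-entropy has no minimizer and each model's logit scale —
hence any confidence-halted comparison — would be an artifact of where the
optimizer stops. The shared ridge gives both models data-determined logit
scales; it stands in for the confidence-calibration matching that a full
treatment would apply per model. Pairs must match in test accuracy within
2 percentage points or the experiment aborts. The headline result is the
fraction of seed-paired experiments (10 seeds, 100 test images each) in
which the LCA-front-end model requires the larger median perturbation MSE.

## Problem sizes

Desk scale throughout: 8 × 8 patches (P = 64), 2×-overcomplete
dictionaries (N = 128) except for the 1×/4× sweep, 5,000 training patches,
120 learning epochs (η = 1.0) for dictionary recovery, 8 neurons × 15
planes per method for population curvature, 20,000 probe images, 10
robustness seeds. The full-scale protocol of the underlying design
(16 × 16 patches, 100 neurons, 300 planes per method — 54 million grid
presentations per overcompleteness level — and 100,000 probe images) is
expressible through `ExperimentConfig` / `paper_scale_config()`; the
presentation-count bookkeeping for it is verified exactly without
evaluating the grids.

## Known limitations

* The generative patches are statistically matched to the model's own
  assumptions; conclusions about natural images require a natural-image
  corpus, which is out of scope.
* The curvature fit is a plain order-2 polynomial on marching-squares
  points; no weighting or robust regression, and one level (0.5) per
  plane.
* Gradients are derivatives of the unrolled dynamics, not implicit
  fixed-point gradients; for small `T` the two can differ.
* The pointwise baselines share the LCA dictionary rather than being
  independently trained autoencoders; independently-trained-weights
  comparisons are approximated, not replicated.
* Confidence calibration between paired classifiers is handled only via
  the shared ridge and equal temperature, not per-model calibration.
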