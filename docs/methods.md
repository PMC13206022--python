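# Methods

## The estimation problem

Hepatic proton-density fat fraction (PDFF) is a proportion in (0, 1)
measured from liver MR. Point estimates alone hide measurement
variability, which matters clinically for borderline steatosis, so this
package treats each slice's fat fraction as a full predictive
distribution: a convolutional network maps a segmented, single-channel
(in-phase Dixon) liver slice to the shape pair (α, β) of a beta
distribution, and the reported quantities are the distribution's mode
(the point estimate) and an equal-tailed interval (the uncertainty).

## Mode-variance parameterization of the beta family

For α, β > 1 the beta density has a unique interior mode

    m = (α − 1) / (α + β − 2),

and variance αβ / ((α+β)² (α+β+1)). A ground-truth PDFF value is
identified with the mode. The mode alone leaves one degree of freedom: all
parameter pairs on the mode line α = 1 + m(s−2), β = 1 + (1−m)(s−2),
s = α + β > 2, share the same mode. Supplying a variance removes it. Along
the mode line the variance is strictly decreasing in the total
concentration s (checked numerically over s ∈ (2, 1000] on a mode grid
before the solver relies on it), so inversion is a monotone 1-D root find,
done with Brent's method on s with bracket doubling (start [2+1e−6, 10],
cap 1e7) and a variance-mismatch tolerance of 1e−10.

Feasibility: under α, β > 1 the variance supremum is 1/12 (the uniform
limit s → 2⁺), for every mode. Requests at or above the attainable maximum
either raise an error naming the maximum (library default) or clamp to 99%
of it (the default inside the calibration loop, which must not crash
mid-training). Input modes are clamped to [1e−4, 1 − 1e−4] so a recorded
fat fraction of exactly zero cannot degenerate the mode line.

## Network

Input slices are masked, cropped to the liver bounding box, bilinearly
resized to 80 × 95 and scaled into [0, 1] by the fixed 16-bit dynamic
range (not per-image min-max, which would erase the absolute-intensity
signal that encodes fat). The regressor is a lightweight CNN:
conv 32 @ 5×5 (valid) → max-pool 2×2 → conv 64 @ 3×3 (valid) → max-pool
2×2 → flatten → dense 128 (softplus) → dense 2 (linear) → 1 + softplus per
output. The final shifted softplus enforces α, β > 1. Convolution
activations are ReLU (a standard default; only the dense-layer softplus is
a structural commitment). Training uses Adam (lr 1e−3), batch 16, 25
epochs, plain MSE on the (α, β) targets. The layers, backward passes and
the optimizer are implemented directly on NumPy arrays (convolutions as
im2col matrix products); with seeds fixed for weight initialization and
batch shuffling, runs are bit-stable on one platform (cross-platform
bit-stability is not promised — BLAS summation order differs).

The softplus head saturates to exactly 1 in floating point for strongly
negative pre-activations; the head is therefore evaluated in float64 and
predictions are floored at 1 + 1e−9 so every predicted distribution is
strictly unimodal.

## Two-stage empirical-variance calibration

Scalar labels are lifted to (α, β) pairs by the mode-variance inversion
with a shared variance:

1. **Stage 0.** An auxiliary variance of 0.0025 — an assumed plausible
   measurement uncertainty, acting as an implicit regularizer — defines
   initial labels (α_i, β_i); the network trains on them.
2. **Stage 1.** The trained model's training-set mode residuals give a
   first empirical variance σ′²₁; every slice is relabeled (same mode, new
   shared variance) to (α′, β′) and the network is retrained.
3. **Stage 2.** The retrained model's residuals give σ′²₂ and the final
   labels (α″, β″); relabeling preserves each slice's ground-truth mode
   exactly. Test-set predictions report the predicted mode and the
   equal-tailed 95% interval of the *predicted* distribution.

Residual variances for relabeling are computed about zero (not about the
residual mean): systematic bias then widens the labels, the conservative
direction for uncertainty.

Empirical variances for relabeling are computed on the **linear fraction
scale**: they parameterize beta distributions over (0, 1), and the
separately reported log-scale σ is not interchangeable with them on unit
grounds. Relabeling variances are floored, and by default the floor *is*
the auxiliary variance: relabeling may widen the labels when residual
dispersion exceeds the assumed measurement uncertainty, but never narrows
them below it. The floor is load-bearing. The mode-variance inversion
maps a shared variance v to a total concentration s ≈ m(1−m)/v, so
variances well below the auxiliary value produce shape targets in the
hundreds to thousands (the fattest slices are hit first — at v = 2.5e−4 a
10% PDFF slice already needs s ≈ 360). Twenty-five epochs of Adam at
learning rate 1e−3 cannot drive the shifted-softplus head across that
range while keeping the two outputs coherent: in experiments at study
scale the retrained network collapses its α output to the lower shape
bound and the point estimates degenerate to near-constants, under fresh
initialization, warm starts, and inverse-variance loss weighting alike.
Lowering the floor is therefore only meaningful together with a larger
training budget.

A corollary worth stating plainly: on data the network fits well — the
synthetic phantom included — the empirical variances fall *below* the
auxiliary value, the floor binds, and the two-stage loop converges at its
first fixed point (the relabeled targets equal the initial ones; stage 2
is a retrain under the same label distribution). The calibration
mechanism genuinely adapts only when residual dispersion exceeds the
assumed measurement uncertainty. A second corollary: when the true
residual dispersion is far below the floored label variance, the
predicted distributions inherit the label variance, and the per-slice 95%
beta intervals are conservative (their empirical coverage approaches 1
rather than 0.95).

Separately from the label variance, the standard deviation σ of
*log-scale* residuals ln(pred) − ln(truth) (natural log; values clamped at
ε = 1e−4 before the log) is recorded from the stage-2 training residuals,
together with their mean. Fat fractions cluster near zero, so relative
errors are the meaningful ones; the σ-bands used for coverage diagnostics
are centered on the training-residual mean (a zero-centered variant is
available, since centering is a genuine free choice).

## Coverage diagnostics

For held-out data, the fraction of log residuals within ±1σ and ±2σ of
the training-residual mean should be ≈68% and ≈95% if residuals are
near-normal and calibration transfers; the fraction of ground-truth values
inside the per-slice 95% beta intervals is the complementary
distributional check. Point accuracy is summarized by MAE (×100,
percentage points) and R², both on the linear fraction scale.

## Synthetic phantom

Real cohort data of this kind are not redistributable, so a seeded phantom
generator stands in. It emulates: 84 subjects contributing 5–8 slices each
at 256 × 192; subject fat fractions from a log-normal law with
exp(μ + σ²/2) = 0.0269 and log-sd 0.8 (right-skewed, median ≈ 2%, upper
tail reaching ≈ 20% — the regime of a lean pediatric cohort); slice-level
relative heterogeneity of 10%; a liver-shaped mask (perturbed ellipse
occupying 20–60% of the frame); parenchymal intensity linear in fat
fraction (baseline 12000 DN, gain 2.0 per unit fat) with Gaussian pixel
noise (300 DN, SNR ≈ 40) and Poisson(3) dark elongated vessel-like
structures per slice. All randomness flows from one seed via per-slice
child generators.

What the phantom does *not* emulate: Dixon signal physics, bias fields,
motion or chemical-shift artifacts, anatomy, or the label noise of a
reference PDFF pipeline. Passing tests on the phantom therefore
demonstrate that the probabilistic framework is correctly implemented and
that its calibration transfers across cohorts drawn from the same law —
not that the trained weights or the reported error magnitudes transfer to
clinical data. Mean masked intensity explains ≥ 80% of fat-fraction
variance by construction (asserted in tests), so the learning task is
genuinely learnable yet noisy enough to leave residual error to calibrate.

## Splitting

Splits are patient-level: subjects are shuffled by seed and assigned
greedily to train/validation/test so cumulative slice counts approach the
70/15/15 slice targets computed by largest-remainder apportionment
(earlier partitions win remainder ties; 473 slices apportion to
331/71/71). No subject straddles partitions; for ≥ 3 subjects all three
partitions are guaranteed non-empty.

## Problem sizes

The study-scale experiment used throughout (tests and the reproduction
script) is an 84-subject training cohort (~550 slices) with 25 epochs per
stage, and an independent 160-subject evaluation cohort (~1000 slices)
from the same generator law for coverage measurement. Reduced
configurations (fewer subjects/epochs) are used for structural and
determinism tests, where statistical power is not the point.

## Known limitations

* The intensity model is linear and single-echo; no claim is made about
  MR physics fidelity.
* The empirical variance is shared across slices (the method models
  homoscedastic measurement dispersion); heteroscedastic or fully learned
  predictive uncertainty is out of scope.
* Only the two-stage path is exercised; the loop generalizes to N stages
  but nothing here validates more than two.
* Cross-platform bit-identity of training is not guaranteed; determinism
  claims are per-platform.
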