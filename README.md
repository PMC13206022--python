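# pdffnet

Probabilistic quantification of hepatic fat from liver MR slices.

Hepatic steatosis is graded by the proton-density fat fraction (PDFF), a
proportion in (0, 1) estimated from MR images. Clinical pipelines usually
report a single number per examination, hiding the measurement
variability that matters most for borderline cases. `pdffnet` instead
treats each segmented, single-channel (in-phase Dixon) liver slice as
evidence about a full *distribution* of fat fraction: a lightweight
convolutional network predicts the shape pair (α, β) of a beta
distribution, the point estimate is the distribution's mode

    m = (α − 1) / (α + β − 2),        α, β > 1,

and the uncertainty is its equal-tailed credible interval. It is intended
for researchers in quantitative liver imaging who want calibrated
uncertainty alongside fat-fraction estimates, and as a reference
implementation of mode-variance beta regression for bounded targets.

Training labels are built by lifting each scalar PDFF value to an (α, β)
pair: the value becomes the mode, and a shared variance — initially an
assumed *auxiliary* measurement variance of 0.0025 — pins down the
remaining degree of freedom via a monotone 1-D root find on the total
concentration α + β. A two-stage calibration loop then re-estimates that
shared variance from the trained model's own training residuals
(σ′², floored at the auxiliary value), relabels, and retrains, yielding
final labels (α″, β″) and per-slice confidence intervals. Calibration is
judged by σ-band coverage: with σ the standard deviation of training-set
log residuals, ≈68% / ≈95% of held-out residuals should fall within
±1σ / ±2σ if calibration transfers.

Real cohorts of this kind are not redistributable, so the package ships a
seeded synthetic phantom generator (84 subjects, 5–8 slices each,
256 × 192, log-normal fat-fraction law with mean ≈ 2.7%) that makes every
stage runnable and testable end to end. See `docs/methods.md` for the
model, the phantom's fidelity limits, and the numerical choices.

## Worked example

Lift a ground-truth fat fraction of 5% to a beta label with the auxiliary
variance, and read back its interval:

```python
from pdffnet import (ModeVarianceSpec, solve_beta_from_mode_variance,
                     beta_mode, beta_credible_interval)

params = solve_beta_from_mode_variance(ModeVarianceSpec(mode=0.05, variance=0.0025))
print(f"alpha={params.alpha:.4f}, beta={params.beta:.4f}")
ci = beta_credible_interval(params, 0.95)
print(f"mode={beta_mode(params):.4f}, 95% interval=[{ci.lower:.4f}, {ci.upper:.4f}]")
```

```
alpha=2.3422, beta=26.5014
mode=0.0500, 95% interval=[0.0131, 0.2028]
```

The distribution peaks exactly at the 5% label, and the interval is wide
(1.3%–20%) because the auxiliary variance is deliberately generous.

The full pipeline — phantom generation, preprocessing, patient-level
70/15/15 split, two-stage calibration, held-out coverage — runs in one
call:

```python
from pdffnet import coverage_experiment

result = coverage_experiment(seed=1)     # ~7 min on one CPU
print(result.state.to_dict())
print(f"test MAE = {result.test_report.mae_pp:.2f} pp")
print(f"eval coverage: ±1σ {result.eval_coverage_1sigma:.1%}, "
      f"±2σ {result.eval_coverage_2sigma:.1%}  (n={result.n_eval_slices})")
```

```
{'auxiliary_variance': 0.0025, 'sigma2_empirical_1': 0.0025,
 'sigma2_empirical_2': 0.0025, 'log_sigma': 0.3255144482101287,
 'log_residual_mean': 0.01472335246209385}
test MAE = 0.37 pp
eval coverage: ±1σ 81.6%, ±2σ 94.3%  (n=1019)
```

Reading this output: the model's training-residual dispersion falls
*below* the auxiliary variance, so the floored empirical variances equal
0.0025 and the loop converges at its first fixed point. Held-out point accuracy is high (0.37 pp mean absolute error
on the test subjects). The ±2σ band covers 94.3% of an independent
1019-slice evaluation cohort — calibration transfers — while the ±1σ band
over-covers (81.6% vs the nominal 68%) because the phantom's log-scale
residuals are heavy-tailed: near-zero-fat slices have large relative
errors, fatty slices tiny ones. `docs/methods.md` discusses both effects.

A command-line interface wraps the same pipeline for on-disk workflows:

```bash
pdffnet generate --seed 7 --data-dir cohort/
pdffnet train    --data-dir cohort/ --output-dir run/
pdffnet predict  --checkpoint run/checkpoint.npz --data-dir cohort/ --out preds.csv
pdffnet evaluate --predictions preds.csv --labels cohort/labels.csv
```

`train` writes the checkpoint, the calibration state (stage variances and
per-stage label tables), per-slice predictions with intervals, an
evaluation report, and a manifest recording every seed and configuration
hash, so a run is reconstructible from its outputs.

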