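"""End-to-end experiment drivers on synthetic cohorts.

These functions wire the phantom generator, preprocessing, the two-stage
calibration loop and the evaluation metrics into single calls, entirely
in memory. They are what the command-line interface, the reproduction
script and the heavier tests all run, so every consumer exercises the
identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calibration import (
    CalibConfig,
    CalibrationState,
    FatFractionLabel,
    SlicePrediction,
    run_two_stage,
)
from .beta_math import beta_mode, beta_credible_interval
from .evaluation import (
    EvaluationReport,
    build_report,
    sigma_band_coverage,
    interval_coverage,
    mae_percentage_points,
    r_squared,
)
from .pnn_model import ModelConfig, predict_params
from .preprocess import ModelInput, prepare_slice, split_by_subject
from .synthetic_phantom import PhantomConfig, iter_cohort

__all__ = ["prepare_cohort", "CoverageResult", "run_calibrated_pipeline", "coverage_experiment"]


def prepare_cohort(config: PhantomConfig) -> tuple[list[ModelInput], list[FatFractionLabel]]:
    """Render a phantom cohort and push every slice through preprocessing."""
    inputs, labels = [], []
    for sl in iter_cohort(config):
        inputs.append(prepare_slice(sl.image, sl.mask, sl.subject_id, sl.slice_index))
        labels.append(FatFractionLabel(sl.subject_id, sl.slice_index, sl.true_pdff))
    return inputs, labels


@dataclass
class CoverageResult:
    """Outcome of a calibrated run plus held-out coverage measurements."""

    state: CalibrationState
    test_report: EvaluationReport
    eval_coverage_1sigma: float
    eval_coverage_2sigma: float
    eval_ci_coverage: float
    eval_mae_pp: float
    eval_r_squared: float
    n_eval_slices: int


def run_calibrated_pipeline(
    seed: int,
    n_subjects: int = 84,
    model_config: ModelConfig | None = None,
    calib_config: CalibConfig | None = None,
    proportions: tuple[float, float, float] = (0.70, 0.15, 0.15),
):
    """Generate a cohort, split it patient-level, and run the two-stage loop.

    All randomness (phantom, split, weight init, batch order) derives from
    ``seed``. Returns ``(model, state, predictions, labels, split)``.
    """
    phantom = PhantomConfig(n_subjects=n_subjects, seed=seed)
    inputs, labels = prepare_cohort(phantom)
    import pandas as pd

    table = pd.DataFrame(
        [{"subject_id": l.subject_id, "slice_index": l.slice_index, "pdff": l.pdff} for l in labels]
    )
    split = split_by_subject(table, proportions, seed=seed + 17)
    mc = model_config or ModelConfig(weight_seed=seed + 29)
    cc = calib_config or CalibConfig(train_seed=seed + 31)
    model, state, predictions = run_two_stage(inputs, labels, split, mc, cc)
    return model, state, predictions, labels, split


def coverage_experiment(
    seed: int,
    n_train_subjects: int = 84,
    n_eval_subjects: int = 160,
    model_config: ModelConfig | None = None,
    calib_config: CalibConfig | None = None,
) -> CoverageResult:
    """Full calibration-transfer experiment.

    Trains and calibrates on one phantom cohort, then measures +-1/2 sigma
    band coverage (sigma and band center taken from the *training*
    residuals) and 95% beta-interval coverage on an independently generated
    evaluation cohort drawn from the same phantom law.
    """
    cc = calib_config or CalibConfig(train_seed=seed + 31)
    model, state, predictions, labels, split = run_calibrated_pipeline(
        seed, n_train_subjects, model_config, cc
    )

    test_ids = {s for s in split.by_subject if split.by_subject[s] == "test"}
    test_truth = [l.pdff for l in labels if l.subject_id in test_ids]
    test_report = build_report(state, predictions, test_truth, cc.epsilon_log, cc.log_base)

    eval_phantom = PhantomConfig(n_subjects=n_eval_subjects, seed=seed + 1_000_003)
    eval_inputs, eval_labels = prepare_cohort(eval_phantom)
    eval_params = predict_params(model, eval_inputs)
    eval_modes = [beta_mode(p) for p in eval_params]
    eval_truth = [l.pdff for l in eval_labels]
    c1, c2 = sigma_band_coverage(
        eval_modes,
        eval_truth,
        state.log_sigma,
        cc.epsilon_log,
        center=state.log_residual_mean,
        base=cc.log_base,
    )
    eval_preds = [
        SlicePrediction(
            subject_id=l.subject_id,
            slice_index=l.slice_index,
            alpha=p.alpha,
            beta=p.beta,
            mode=m,
            interval=beta_credible_interval(p, cc.ci_level),
        )
        for l, p, m in zip(eval_labels, eval_params, eval_modes)
    ]
    ci_cov = interval_coverage(eval_preds, eval_truth)
    return CoverageResult(
        state=state,
        test_report=test_report,
        eval_coverage_1sigma=c1,
        eval_coverage_2sigma=c2,
        eval_ci_coverage=ci_cov,
        eval_mae_pp=mae_percentage_points(eval_modes, eval_truth),
        eval_r_squared=r_squared(eval_modes, eval_truth),
        n_eval_slices=len(eval_labels),
    )
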