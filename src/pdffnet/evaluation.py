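"""Accuracy and calibration diagnostics for fat-fraction predictions.

Two complementary views of calibration are reported. The sigma-band view
works on log-scale residuals: with sigma estimated from training residuals,
a well-calibrated model puts roughly 68% of held-out residuals within
+-1 sigma and 95% within +-2 sigma of the training-residual mean. The
interval view asks how often the ground truth falls inside each slice's
equal-tailed beta interval. Point accuracy is summarized by the mean
absolute error in percentage points and the coefficient of determination,
both on the linear fraction scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import CalibrationState, SlicePrediction, _log_residuals

__all__ = [
    "EvaluationReport",
    "sigma_band_coverage",
    "mae_percentage_points",
    "r_squared",
    "interval_coverage",
    "build_report",
]


@dataclass
class EvaluationReport:
    """The metric suite for one evaluation set."""

    log_sigma: float
    coverage_1sigma: float
    coverage_2sigma: float
    mae_pp: float
    r_squared: float
    ci_coverage: float
    n_slices: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _check_aligned(pred, true):
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("predicted and true values must align and be non-empty")
    return pred, true


def sigma_band_coverage(
    predicted_modes: Sequence[float],
    true_modes: Sequence[float],
    sigma: float,
    epsilon: float = 1e-4,
    *,
    center: float = 0.0,
    base: float | None = None,
) -> tuple[float, float]:
    """Fractions of log residuals within +-1 and +-2 sigma of ``center``.

    ``sigma`` and ``center`` normally come from the *training* residual
    distribution (``CalibrationState.log_sigma`` / ``log_residual_mean``),
    so that coverage on held-out data is a genuine calibration check;
    ``center=0`` assesses bands centered at zero instead.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pred, true = _check_aligned(predicted_modes, true_modes)
    r = np.abs(_log_residuals(pred, true, epsilon, base) - center)
    return float(np.mean(r <= sigma)), float(np.mean(r <= 2.0 * sigma))


def mae_percentage_points(predicted_modes: Sequence[float], true_modes: Sequence[float]) -> float:
    """Mean absolute error, scaled from fraction to percentage points."""
    pred, true = _check_aligned(predicted_modes, true_modes)
    return 100.0 * float(np.mean(np.abs(pred - true)))


def r_squared(predicted_modes: Sequence[float], true_modes: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (can be negative)."""
    pred, true = _check_aligned(predicted_modes, true_modes)
    if pred.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((true - true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant ground truth: coefficient of determination undefined")
    return 1.0 - float(np.sum((true - pred) ** 2)) / ss_tot


def interval_coverage(predictions: Sequence[SlicePrediction], true_modes: Sequence[float]) -> float:
    """Fraction of ground-truth values inside their predicted interval."""
    if len(predictions) != len(true_modes) or not predictions:
        raise ValueError("predictions and true modes must align and be non-empty")
    hits = [p.interval.contains(float(t)) for p, t in zip(predictions, true_modes)]
    return float(np.mean(hits))


def build_report(
    state: CalibrationState,
    predictions: Sequence[SlicePrediction],
    true_modes: Sequence[float],
    epsilon: float = 1e-4,
    base: float | None = None,
) -> EvaluationReport:
    """Aggregate every metric for one prediction set against its ground truth.

    Sigma bands use the training-set sigma and residual mean stored in the
    calibration state.
    """
    if state.log_sigma is None or state.log_residual_mean is None:
        raise ValueError("calibration state has no log-scale residual summary")
    pred_modes = [p.mode for p in predictions]
    c1, c2 = sigma_band_coverage(
        pred_modes, true_modes, state.log_sigma, epsilon, center=state.log_residual_mean, base=base
    )
    return EvaluationReport(
        log_sigma=state.log_sigma,
        coverage_1sigma=c1,
        coverage_2sigma=c2,
        mae_pp=mae_percentage_points(pred_modes, true_modes),
        r_squared=r_squared(pred_modes, true_modes),
        ci_coverage=interval_coverage(predictions, true_modes),
        n_slices=len(predictions),
    )
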