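"""Label construction, empirical variances and the two-stage loop."""

import math

import numpy as np
import pytest

from pdffnet.beta_math import beta_mode, beta_variance
from pdffnet.calibration import (
    CalibConfig,
    FatFractionLabel,
    empirical_variance,
    labels_from_pdff,
    log_residual_sigma,
    run_two_stage,
)
from pdffnet.pnn_model import ModelConfig
from pdffnet.preprocess import split_by_subject


def _labels(pdffs):
    return [FatFractionLabel("S", i, p) for i, p in enumerate(pdffs)]


class TestLabelsFromPdff:
    def test_symmetric_inversion(self):
        (p,) = labels_from_pdff(_labels([0.5]), 0.05)
        assert p.alpha == pytest.approx(2.0, abs=1e-9)
        assert p.beta == pytest.approx(2.0, abs=1e-9)

    def test_pure_function_of_pdff(self):
        a, b = labels_from_pdff(_labels([0.02, 0.02]), 0.0025)
        assert (a.alpha, a.beta) == (b.alpha, b.beta)

    def test_low_fat_with_auxiliary_variance(self):
        # frozen from the dense grid-search oracle over total concentration
        (p,) = labels_from_pdff(_labels([0.05]), 0.0025)
        assert p.alpha == pytest.approx(2.3422, abs=1e-3)
        assert p.beta == pytest.approx(26.502, abs=1e-2)
        assert beta_mode(p) == pytest.approx(0.05, abs=1e-12)
        assert beta_variance(p) == pytest.approx(0.0025, abs=1e-10)

    def test_zero_pdff_clamped_not_crashed(self):
        (p,) = labels_from_pdff(_labels([0.0]), 0.0025)
        assert beta_mode(p) == pytest.approx(1e-4, abs=1e-12)

    def test_shared_variance_holds_across_modes(self):
        pdffs = [0.01, 0.03, 0.1, 0.3]
        for p in labels_from_pdff(_labels(pdffs), 0.0025):
            assert beta_variance(p) == pytest.approx(0.0025, abs=1e-10)


class TestEmpiricalVariance:
    def test_arithmetic(self):
        pred = np.array([0.01, -0.01, 0.02, -0.02]) + 0.1
        true = np.full(4, 0.1)
        assert empirical_variance(pred, true) == pytest.approx(0.00025, rel=1e-12)

    def test_floor_on_perfect_predictions(self):
        assert empirical_variance([0.1, 0.2], [0.1, 0.2]) == 1e-6

    def test_constant_residual(self):
        assert empirical_variance([0.13, 0.23], [0.1, 0.2]) == pytest.approx(0.03**2, rel=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            empirical_variance([0.1], [0.1, 0.2])


class TestLogResidualSigma:
    def test_symmetric_relative_errors(self):
        true = np.full(100, 0.05)
        pred = true * np.where(np.arange(100) % 2 == 0, math.e**0.1, math.e**-0.1)
        sigma, mean = log_residual_sigma(pred, true)
        assert sigma == pytest.approx(0.1, abs=1e-12)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_perfect_predictions(self):
        sigma, _ = log_residual_sigma([0.1, 0.2], [0.1, 0.2])
        assert sigma == 0.0

    def test_constant_multiplicative_bias_centered_out(self):
        true = np.array([0.01, 0.05, 0.2])
        sigma, mean = log_residual_sigma(true * math.e**0.3, true)
        assert sigma == pytest.approx(0.0, abs=1e-12)
        assert mean == pytest.approx(0.3, abs=1e-12)

    def test_configurable_base(self):
        true = np.array([0.01, 0.1])
        pred = true * 10.0
        _, mean10 = log_residual_sigma(pred, true, base=10.0)
        assert mean10 == pytest.approx(1.0, abs=1e-12)


class TestTwoStage:
    def test_state_fully_populated(self, small_pipeline_run):
        state = small_pipeline_run["state"]
        n = len(small_pipeline_run["labels"])
        assert state.sigma2_empirical_1 > 0
        assert state.sigma2_empirical_2 > 0
        assert state.log_sigma is not None and np.isfinite(state.log_sigma)
        for stage in ("initial", "relabel_1", "final"):
            assert len(state.stage_labels[stage]) == n

    def test_stage_labels_carry_the_stage_variance(self, small_pipeline_run):
        state = small_pipeline_run["state"]
        for stage, variance in (
            ("initial", state.auxiliary_variance),
            ("relabel_1", state.sigma2_empirical_1),
            ("final", state.sigma2_empirical_2),
        ):
            for p in state.stage_labels[stage]:
                assert beta_variance(p) == pytest.approx(variance, abs=1e-9)

    def test_final_labels_preserve_ground_truth_modes(self, small_pipeline_run):
        state = small_pipeline_run["state"]
        labels = small_pipeline_run["labels"]
        clamp = 1e-4
        for lab, p in zip(labels, state.stage_labels["final"]):
            expected = min(max(lab.pdff, clamp), 1 - clamp)
            assert beta_mode(p) == pytest.approx(expected, abs=1e-12)

    def test_predictions_cover_test_partition(self, small_pipeline_run):
        split = small_pipeline_run["split"]
        labels = small_pipeline_run["labels"]
        preds = small_pipeline_run["predictions"]
        n_test = sum(1 for l in labels if split.partition_of(l.subject_id) == "test")
        assert len(preds) == n_test
        for p in preds:
            assert p.alpha > 1 and p.beta > 1
            assert p.mode == pytest.approx((p.alpha - 1) / (p.alpha + p.beta - 2), abs=1e-10)
            assert 0 <= p.interval.lower < p.interval.upper <= 1
            assert p.interval.level == 0.95

    def test_zero_epochs_pipeline_structurally_sound(self, tiny_cohort):
        import pandas as pd

        inputs, labels = tiny_cohort
        table = pd.DataFrame(
            [{"subject_id": l.subject_id, "slice_index": l.slice_index, "pdff": l.pdff} for l in labels]
        )
        split = split_by_subject(table, seed=0)
        _, state, preds = run_two_stage(
            inputs, labels, split, ModelConfig(epochs=0, weight_seed=1), CalibConfig(train_seed=1)
        )
        assert state.sigma2_empirical_1 > 0 and state.sigma2_empirical_2 > 0
        assert len(preds) > 0

    def test_determinism_of_full_loop(self, tiny_cohort):
        import pandas as pd

        inputs, labels = tiny_cohort
        table = pd.DataFrame(
            [{"subject_id": l.subject_id, "slice_index": l.slice_index, "pdff": l.pdff} for l in labels]
        )
        split = split_by_subject(table, seed=0)

        def run():
            return run_two_stage(
                inputs, labels, split, ModelConfig(epochs=2, weight_seed=4), CalibConfig(train_seed=6)
            )

        _, s1, p1 = run()
        _, s2, p2 = run()
        assert s1.to_dict() == s2.to_dict()
        assert [(p.alpha, p.beta, p.mode) for p in p1] == [(p.alpha, p.beta, p.mode) for p in p2]

    def test_state_serialization_round_trip(self, small_pipeline_run, tmp_path):
        import json

        state = small_pipeline_run["state"]
        state.save(tmp_path, small_pipeline_run["labels"])
        loaded = json.loads((tmp_path / "calibration_state.json").read_text())
        assert loaded == state.to_dict()
        assert (tmp_path / "labels_final.csv").exists()
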