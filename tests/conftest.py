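import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_phantom_config():
    from pdffnet.synthetic_phantom import PhantomConfig

    return PhantomConfig(n_subjects=6, seed=99)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_phantom_config):
    """A small prepared cohort shared across model and calibration tests."""
    from pdffnet.experiments import prepare_cohort

    return prepare_cohort(tiny_phantom_config)


@pytest.fixture(scope="session")
def small_pipeline_run():
    """A reduced but complete two-stage run: 12 subjects, 4 epochs per stage."""
    from pdffnet.experiments import run_calibrated_pipeline
    from pdffnet.pnn_model import ModelConfig
    from pdffnet.calibration import CalibConfig

    model, state, predictions, labels, split = run_calibrated_pipeline(
        seed=7,
        n_subjects=12,
        model_config=ModelConfig(epochs=4, weight_seed=3),
        calib_config=CalibConfig(train_seed=5),
    )
    return {"model": model, "state": state, "predictions": predictions, "labels": labels, "split": split}
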