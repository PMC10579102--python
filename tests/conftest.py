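import numpy as np
import pytest

from rltitr.patient_model import PatientModelConfig, TrainConfig, train_patient_model
from rltitr.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Noiseless 60-patient, 3-day cohort with known latents."""
    cfg = CohortConfig(n_patients=60, n_days=3, noise_sd=0.0, seed=7)
    trajs, latents = generate_cohort(cfg)
    return cfg, trajs, latents


@pytest.fixture(scope="session")
def trained_patient_model(small_cohort):
    """A quickly trained scaled-down patient model shared across tests."""
    _, trajs, _ = small_cohort
    model, history = train_patient_model(
        trajs,
        PatientModelConfig.scaled_down(),
        TrainConfig.scaled_down(epochs=12, seed=0),
    )
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
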