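import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from strideval import (
    DeviceErrorModel,
    SprintParams,
    degrade_to_device,
    simulate_criterion_trial,
)


@pytest.fixture(scope="session")
def default_params() -> SprintParams:
    return SprintParams(seed=42)


@pytest.fixture(scope="session")
def clean_trial(default_params):
    """One simulated trial without marker noise (exact geometry)."""
    import dataclasses

    params = dataclasses.replace(default_params, marker_noise_sd=0.0)
    return simulate_criterion_trial(params, trial_id="T-clean")


@pytest.fixture(scope="session")
def noisy_trial(default_params):
    return simulate_criterion_trial(default_params, trial_id="T-noisy")


@pytest.fixture(scope="session")
def identity_device(clean_trial):
    return degrade_to_device(clean_trial, DeviceErrorModel.identity(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
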