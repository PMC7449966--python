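import numpy as np
import pytest

from liverspec.spectra_forward import default_forward
from liverspec.sto2_inverse import (build_training_set,
                                    train_saturation_regressor)
from liverspec.synthetic_cohort import extract_features, generate_cohort

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def forward():
    """Shared accelerated forward model (white-MC baselines built once)."""
    fw = default_forward()
    fw._ensure_baselines()
    return fw


@pytest.fixture(scope="session")
def sto2_model(forward):
    """Noise-robust saturation regressor at the default training settings."""
    ts = build_training_set(n_samples=2000, seed=0, noise_frac=0.01,
                            noise_replicas=6, forward=forward)
    return train_saturation_regressor(ts, seed=0)


@pytest.fixture(scope="session")
def default_cohort(forward):
    return generate_cohort(seed=42, forward=forward)


@pytest.fixture(scope="session")
def cohort_features(default_cohort, sto2_model):
    return extract_features(default_cohort, sto2_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
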