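import numpy as np
import pytest

from emgadapt import GeneratorConfig, generate_dataset
from emgadapt.synthgen import ShiftProfile


@pytest.fixture(scope="session")
def tiny_cfg() -> GeneratorConfig:
    """Small config for fast unit tests (8 subjects: 5 baseline, 3 shifted)."""
    return GeneratorConfig(n_subjects=8, n_classes=5, n_trials_per_class=7,
                           n_channels=4, trial_length=500, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return generate_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """Mid-size config for experiment-level tests."""
    return GeneratorConfig(n_subjects=10, n_classes=6, n_trials_per_class=8,
                           n_channels=4, trial_length=600, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The full default study conditions: 14 subjects (11 baseline / 3
    shifted), 15 classes, 20 trials, 8 channels, 2000 samples at 500 Hz."""
    return generate_dataset(GeneratorConfig(seed=1))
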