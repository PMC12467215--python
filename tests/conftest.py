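import numpy as np
import pytest

from ecgcoattn.model_core import ModelConfig
from ecgcoattn.synthetic_ecg import SynthConfig, synth_dataset


@pytest.fixture(scope="session")
def small_superclass_records():
    """60 multilabel 5-superclass records, 100 Hz, short duration."""
    cfg = SynthConfig(n_records=60, fs=100, duration=4.0, noise_sd=0.03,
                      seed=101)
    return synth_dataset(cfg), cfg


@pytest.fixture(scope="session")
def clean_rhythm_records():
    """Noise-free exclusive rhythm records at 500 Hz with known R peaks."""
    cfg = SynthConfig(n_records=24, fs=500, duration=10.0, noise_sd=0.0,
                      class_scheme="rhythm", label_mode="exclusive", seed=55)
    return synth_dataset(cfg), cfg


@pytest.fixture()
def tiny_model_cfg():
    """A model small enough for shape/oracle tests."""
    return ModelConfig(n_leads=4, input_len=64, n_classes=3, stem_channels=3,
                       ltcar1_channels=4, ltcar2_channels=5, branch_channels=4,
                       head_hidden=8, reduction_r=2, dropout_p=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
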