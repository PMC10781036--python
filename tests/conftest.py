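import dataclasses

import numpy as np
import pytest

from ppg_bioauth.model import ModelConfig
from ppg_bioauth.preprocess import PreprocessConfig
from ppg_bioauth.scalogram import ScalogramConfig
from ppg_bioauth.synth import NoiseConfig, SynthIdentity, synth_cohort


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """Miniature hybrid-model config for fast architecture tests."""
    return ModelConfig(
        profile="desk", image_side=16, patch_size=4, hidden_dim=8,
        mixer_depth=2, mixer_kernel=3, cvt_conv_layers=2,
        cvt_channel_plan=(4, 8), n_pool=2, n_tokens=2, token_dim=16,
        n_heads=2, mlp_hidden=16, n_classes=3, seed=0,
    )


@pytest.fixture
def steady_identity():
    """Jitter-free 60 bpm identity with a small dicrotic wave."""
    return SynthIdentity(
        identity_id=0, heart_rate_bpm=(60.0, 0.0), systolic_amplitude=1.0,
        systolic_width_s=0.1, dicrotic_amplitude=0.3, dicrotic_delay_s=0.3,
        seed=0,
    )


@pytest.fixture(scope="session")
def desk_dataset():
    """The scaled-down identification cohort: 8 well-separated identities,
    60 five-second records each at 250 Hz, default noise, one segment per
    record after preprocessing."""
    from ppg_bioauth.pipeline import records_to_dataset

    records = synth_cohort(8, 60, 5.0, 250.0, NoiseConfig(), seed=0,
                           separated=True)
    scal = ScalogramConfig(n_freq_bins=64, freq_min_hz=0.5, freq_max_hz=25.0,
                           image_side=64)
    return records_to_dataset(records, PreprocessConfig(), scal)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic image dataset for protocol (not accuracy) tests."""
    rng = np.random.default_rng(0)
    n_classes, per_class = 4, 25
    images, labels = [], []
    for c in range(n_classes):
        for _ in range(per_class):
            img = rng.normal(0, 0.1, size=(16, 16)) + c * 0.25
            images.append(np.clip(img, 0, 1))
            labels.append(c)
    from ppg_bioauth.train_eval import Dataset

    return Dataset(np.stack(images).astype(np.float32), np.array(labels))
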