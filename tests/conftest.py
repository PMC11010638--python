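"""Shared fixtures: small synthetic datasets built once per session."""

import numpy as np
import pytest

from musemo.features import build_feature_matrix
from musemo.preprocess import preprocess_dataset
from musemo.synth import (
    SyntheticDatasetSpec,
    default_profiles,
    make_dataset,
)


@pytest.fixture(scope="session")
def tiny_spec():
    """4 classes x 4 trials, 8 channels, 10-s trials at 128 Hz."""
    return SyntheticDatasetSpec(
        profiles=default_profiles(),
        n_trials_per_class=4,
        n_channels=8,
        trial_seconds=10.0,
        fs=128.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return make_dataset(tiny_spec)


@pytest.fixture(scope="session")
def tiny_segments(tiny_dataset):
    recordings, ratings = tiny_dataset
    return preprocess_dataset(recordings, ratings)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_segments):
    return build_feature_matrix(tiny_segments)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
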