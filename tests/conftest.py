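import numpy as np
import pytest

from facemmg import synth
from facemmg.calibration import enumerate_pairs
from facemmg.features import build_feature_matrix


@pytest.fixture(scope="session")
def small_separable_dataset():
    """2 subjects x 3 sessions x 2 reps on the separable preset (132 events)."""
    return synth.generate_protocol(
        n_subjects=2, n_sessions=3, reps=2, seed=7,
        config=synth.difficulty_presets("separable"))


@pytest.fixture(scope="session")
def small_tables(small_separable_dataset):
    return synth.calibration_tables(small_separable_dataset)


@pytest.fixture(scope="session")
def small_feature_matrix(small_separable_dataset, small_tables):
    return build_feature_matrix(
        small_separable_dataset, enumerate_pairs("all"), small_tables)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
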