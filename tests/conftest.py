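"""Shared fixtures: small synthetic sessions and feature matrices.

Sessions here are deliberately smaller than the full protocol (shorter
holds, fewer repetitions) so the suite stays fast; tests that depend on the
full design counts build their own sessions.
"""

import numpy as np
import pandas as pd
import pytest

import wristemg as we
from wristemg.features import FeatureMatrix


@pytest.fixture(scope="session")
def small_config():
    return we.SessionConfig(seed=101, reps_per_position=3, hold_s=0.6)


@pytest.fixture(scope="session")
def small_trials(small_config):
    return we.generate_session(small_config)


@pytest.fixture(scope="session")
def small_filtered(small_config, small_trials):
    return [we.preprocess_trial(t) for t in small_trials]


@pytest.fixture(scope="session")
def small_features(small_filtered):
    """Combined-muscle TDAR+POS matrix of the small session."""
    return we.extract(small_filtered, include_pos=True)


@pytest.fixture(scope="session")
def bank_config():
    """Session with the protocol's 6 repetitions (shorter holds) so the
    ratio targets have realistic sampling noise."""
    return we.SessionConfig(seed=202, reps_per_position=6, hold_s=1.0)


@pytest.fixture(scope="session")
def bank_features(bank_config):
    trials = [we.preprocess_trial(t) for t in we.generate_session(bank_config)]
    return we.extract(trials)


def feature_matrix_from_arrays(X, y, positions=0, reps=0):
    """Build a FeatureMatrix from bare arrays for classifier fixtures."""
    n = len(y)
    labels = pd.DataFrame(
        {
            "class": y,
            "position_index": np.broadcast_to(positions, n),
            "rep_index": np.broadcast_to(reps, n),
            "window_index": np.arange(n),
        }
    )
    cols = [f"f{i}" for i in range(X.shape[1])]
    return FeatureMatrix(X=np.asarray(X, float), columns=cols, labels=labels)


@pytest.fixture
def make_fm():
    return feature_matrix_from_arrays
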