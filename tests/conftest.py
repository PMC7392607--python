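import numpy as np
import pytest

import tandemflow as tf


def make_trajectory(positions, trial_id="t0", role="leader", frame_rate=1.0):
    return tf.RawTrajectory(trial_id, role, np.asarray(positions, float), frame_rate)


def make_pair(leader_pos, follower_pos, trial_id="t0", frame_rate=1.0,
              species="", body_length_mm=1.0):
    lead = make_trajectory(leader_pos, trial_id, "leader", frame_rate)
    foll = make_trajectory(follower_pos, trial_id, "follower", frame_rate)
    return tf.TandemPair(lead, foll, species=species, body_length_mm=body_length_mm)


@pytest.fixture(scope="session")
def ant_dataset():
    """Small ant-protocol dataset shared across tests (read-only)."""
    cfg = tf.ant_config(seed=7, duration_s=300.0, frame_rate=10.0)
    return tf.simulate_dataset(cfg, n_pairs=8)


@pytest.fixture(scope="session")
def termite_dataset():
    cfg = tf.termite_config(seed=7, duration_s=300.0, frame_rate=10.0)
    return tf.simulate_dataset(cfg, n_pairs=8)


@pytest.fixture(scope="session")
def independent_dataset():
    cfg = tf.independent_config(seed=7, duration_s=300.0, frame_rate=10.0)
    return tf.simulate_dataset(cfg, n_pairs=8)


@pytest.fixture(scope="session")
def ant_encoded(ant_dataset):
    sub = tf.prepare_dataset(ant_dataset, period_s=0.5)
    return {
        "rotation": tf.encode_dataset(sub, "rotation"),
        "pausing": tf.encode_dataset(sub, "pausing"),
        "dataset": sub,
    }
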