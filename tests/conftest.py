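"""Shared fixtures: small synthetic datasets and reduced model configs."""

from __future__ import annotations

import numpy as np
import pytest

import topofnirs as tf
from topofnirs.train import prepare_inputs


SMALL_MODEL = dict(d_model=16, n_heads=2, ffn_dim=32, lstm_hidden=16, mlp_hidden=32)


@pytest.fixture(scope="session")
def small_model_config():
    return tf.ModelConfig(**SMALL_MODEL)


@pytest.fixture(scope="session")
def tiny_epoch_set():
    """Four-pair, one-subject dataset small enough for fast unit tests."""
    cfg = tf.two_class_block_config(
        n_pairs=4, n_subjects=1, n_trials_per_class=3, seed=5
    )
    ds = tf.simulate_dataset(cfg)
    pre = tf.PreprocessConfig(filter_kind="lowpass", band=(0.0, 2.0))
    return tf.concatenate_epoch_sets(
        [tf.preprocess_recording(r, pre) for r in ds.recordings]
    )


@pytest.fixture(scope="session")
def tiny_inputs(tiny_epoch_set):
    return prepare_inputs(tiny_epoch_set)


@pytest.fixture(scope="session")
def recovery_epoch_set():
    """The two-class connectivity-recovery dataset: 2 subjects, 10 pairs,
    disjoint coupling blocks, 100 epochs per class per subject."""
    cfg = tf.two_class_block_config(
        n_pairs=10, n_subjects=2, n_trials_per_class=10, seed=7
    )
    ds = tf.simulate_dataset(cfg)
    pre = tf.PreprocessConfig(filter_kind="lowpass", band=(0.0, 2.0))
    return tf.concatenate_epoch_sets(
        [tf.preprocess_recording(r, pre) for r in ds.recordings]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
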