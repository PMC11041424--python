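"""Shared fixtures: small pretrained backbone and full pipeline runs.

The heavy objects (pretrained backbone, LOO-adapted cohorts) are built once
per session and shared across unit and acceptance tests.  All seeds are
fixed constants so every run is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

import typefatigue as tf

SEED = 1

#: reduced-epoch adaptation schedule used throughout the suite
TEST_ADAPT = dict(epochs=15, batches_per_epoch=50, triplets_per_batch=64)


#: desk-scale pretraining schedule: dropout off (the architecture's dropout
#: rates regularise corpus-scale training and only add noise at this size)
PRETRAIN_SCHED = dict(
    epochs=4,
    batches_per_epoch=12,
    triplets_per_batch=48,
    learning_rate=3e-4,
    recurrent_dropout=0.0,
    inter_layer_dropout=0.0,
)


@pytest.fixture(scope="session")
def pretrained_backbone() -> tf.TypingEmbedder:
    """Identity-pretrained backbone on a desk-scale synthetic corpus."""
    corpus = tf.simulate_pretraining_corpus(
        n_users=20, sessions_per_user=8, keys_per_session=60, seed=SEED
    )
    return tf.pretrain_backbone(corpus, seed=SEED, **PRETRAIN_SCHED)


def run_cohort_pipeline(backbone, population=None, seed=SEED + 1):
    """Simulate a supervised cohort and run the full LOO adaptation."""
    corpus = tf.simulate_supervised_cohort(
        n_participants=14, population=population, seed=seed
    )
    windows = tf.featurize_sessions(corpus.sessions)
    cfg = tf.AdaptationConfig(seed=SEED, **TEST_ADAPT)
    folds = tf.loo_protocol(windows, backbone, cfg)
    pairs = tf.build_pairs(folds, max_pairs_per_class=100, rng=SEED)
    report = tf.roc_analysis(pairs)
    return {
        "corpus": corpus,
        "windows": windows,
        "folds": folds,
        "pairs": pairs,
        "report": report,
    }


@pytest.fixture(scope="session")
def strong_pipeline(pretrained_backbone):
    """Full DML pipeline on the default (strong fatigue effect) cohort."""
    return run_cohort_pipeline(pretrained_backbone)


@pytest.fixture(scope="session")
def null_pipeline(pretrained_backbone):
    """Full DML pipeline on a zero-fatigue-effect cohort (same seed)."""
    pop = tf.PopulationConfig(mean_scale=1.0, sd_scale=1.0)
    return run_cohort_pipeline(pretrained_backbone, population=pop)


@pytest.fixture(scope="session")
def tiny_cohort_windows():
    """Small labelled window set for cheap adaptation unit tests."""
    corpus = tf.simulate_supervised_cohort(
        n_participants=4, session_minutes=3.0, seed=SEED
    )
    return tf.featurize_sessions(corpus.sessions)
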