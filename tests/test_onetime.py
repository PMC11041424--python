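"""Pair construction, ROC analysis, operating point, baselines."""

import numpy as np
import pytest
from scipy.stats import norm

import typefatigue as tf
from typefatigue.adaptation import LOOFold
from typefatigue.onetime import (
    CHANGE,
    NO_CHANGE,
    baseline_feature_table,
    build_pairs,
    operating_point,
    roc_analysis,
    summary_features,
)
from typefatigue.sessions import FATIGUE, REST


def _fold(pid, labels, rng, gap=0.0):
    emb = rng.standard_normal((len(labels), 8))
    emb[np.array(labels) == FATIGUE] += gap
    return LOOFold(
        participant_id=pid,
        head=None,
        heldout_embeddings=emb,
        heldout_labels=np.array(labels),
        train_rest_embeddings=rng.standard_normal((5, 8)),
        train_fatigue_embeddings=rng.standard_normal((5, 8)) + gap,
    )


class TestBuildPairs:
    def test_enumeration_two_plus_two(self):
        rng = np.random.default_rng(0)
        fold = _fold("p", [REST, REST, FATIGUE, FATIGUE], rng)
        pairs = build_pairs([fold], policy="all")
        truths = [p.truth for p in pairs]
        assert len(pairs) == 6
        assert truths.count(CHANGE) == 4 and truths.count(NO_CHANGE) == 2

    def test_never_mixes_participants(self):
        rng = np.random.default_rng(1)
        folds = [_fold(f"p{i}", [REST, FATIGUE, REST, FATIGUE], rng) for i in range(6)]
        pairs = build_pairs(folds, policy="all")
        assert {p.participant_id for p in pairs} == {f"p{i}" for i in range(6)}
        # distances recomputed per participant only: spot-check one pair
        f0 = folds[0]
        d01 = float(np.linalg.norm(f0.heldout_embeddings[0] - f0.heldout_embeddings[1]))
        assert any(p.participant_id == "p0" and abs(p.distance - d01) < 1e-12 for p in pairs)

    def test_balanced_policy_caps_classes(self):
        rng = np.random.default_rng(2)
        fold = _fold("p", [REST] * 10 + [FATIGUE] * 10, rng)
        pairs = build_pairs([fold], policy="balanced", max_pairs_per_class=7, rng=0)
        truths = [p.truth for p in pairs]
        assert truths.count(CHANGE) == 7 and truths.count(NO_CHANGE) == 7


class TestROCAnalysis:
    def test_perfect_separation(self):
        y = np.array([0] * 50 + [1] * 50)
        s = np.concatenate([np.zeros(50), np.ones(50)])
        rep = roc_analysis((y, s))
        assert rep.auc_percent == 100.0
        assert rep.sensitivity == 100.0 and rep.specificity == 100.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=2000)
        s = rng.uniform(size=2000)
        rep = roc_analysis((y, s))
        assert 45.0 <= rep.auc_percent <= 55.0

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=500)
        s = rng.normal(size=500) + y
        a = roc_analysis((y, s)).auc_percent
        b = roc_analysis((y, np.exp(3 * s))).auc_percent
        assert a == pytest.approx(b)

    def test_roc_monotone(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=300)
        s = rng.normal(size=300) + 0.5 * y
        rep = roc_analysis((y, s))
        assert np.all(np.diff(rep.roc_fpr) >= 0)
        assert np.all(np.diff(rep.roc_tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis((np.ones(5, dtype=int), np.arange(5.0)))

    def test_pooled_equals_averaged_for_identical_participants(self):
        """Same score distribution across participants: aggregations agree."""
        rng = np.random.default_rng(6)
        y = np.tile([0, 1], 400)
        s = np.where(y == 1, 2.0, 0.0) + 0.0  # deterministic separation
        pid = np.repeat(["a", "b"], 400)
        pooled = roc_analysis((y, s, pid), aggregation="pooled").auc_percent
        avg = roc_analysis((y, s, pid), aggregation="per_participant_averaged").auc_percent
        assert pooled == pytest.approx(avg, abs=0.5)


class TestOperatingPoint:
    def test_symmetric_gaussian_overlap(self):
        """Equal-variance Gaussians: corner point has sens ~ spec."""
        rng = np.random.default_rng(7)
        n = 10_000
        s = np.concatenate([rng.normal(0, 1, n), rng.normal(1.5, 1, n)])
        y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
        rep = roc_analysis((y, s))
        assert rep.sensitivity == pytest.approx(rep.specificity, abs=2.0)
        # and both near the closed-form value Phi(mu/2)
        expected = 100 * norm.cdf(0.75)
        assert rep.sensitivity == pytest.approx(expected, abs=2.0)

    def test_f1_definition_consistent(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 500)
        s = rng.normal(size=500) + y
        rep = roc_analysis((y, s))
        f1 = 2 * rep.precision * rep.sensitivity / (rep.precision + rep.sensitivity)
        assert rep.f1 == pytest.approx(f1)


class TestBaselines:
    def test_feature_table_shape(self):
        corpus = tf.simulate_supervised_cohort(n_participants=2, session_minutes=2.0, seed=0)
        X, y, pids = baseline_feature_table(corpus.sessions, setup="150keys")
        assert X.shape[1] == 20  # 4 timing features x 5 statistics
        assert len(X) == len(y) == len(pids)

    def test_summary_features_values(self):
        m = np.array([[1.0, 0, 0, 0], [3.0, 0, 0, 0]])
        f = summary_features(m)
        assert f[0] == pytest.approx(2.0)  # mean hold
        assert f[4] == pytest.approx(2.0)  # median hold
        assert f[8] == pytest.approx(np.sqrt(2.0))  # sd hold

    def test_five_minute_windows_use_more_keys(self):
        corpus = tf.simulate_supervised_cohort(n_participants=2, session_minutes=10.0, seed=1)
        X150, _, _ = baseline_feature_table(corpus.sessions, setup="150keys")
        X5, _, _ = baseline_feature_table(corpus.sessions, setup="5min")
        assert len(X5) < len(X150)  # fewer, larger samples

    def test_strong_effect_baselines_beat_chance(self, strong_pipeline):
        reports = tf.baseline_classifiers(
            strong_pipeline["corpus"].sessions, setup="150keys", seed=0
        )
        assert set(reports) == {"random_forest", "svm", "knn"}
        for rep in reports.values():
            assert rep.auc_percent > 60.0
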