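"""Fatigue adaptation: distances, triplet sampling, heads, LOO protocol."""

import numpy as np
import pytest

import typefatigue as tf
from typefatigue.adaptation import (
    AdaptationConfig,
    FatigueMetricHead,
    SoftmaxFatigueHead,
    euclidean_distance,
    loo_protocol,
    sample_triplets,
    triplet_loss,
)
from typefatigue.sessions import FATIGUE, REST

SMALL_CFG = AdaptationConfig(epochs=3, batches_per_epoch=10, triplets_per_batch=16, seed=0)


class TestEuclideanDistance:
    def test_identity_and_pythagorean(self):
        z = np.zeros(128)
        v = z.copy()
        v[0], v[1] = 3.0, 4.0
        assert euclidean_distance(z, z) == 0.0
        assert euclidean_distance(z, v) == pytest.approx(5.0)

    def test_symmetry_and_mismatch(self):
        a, b = np.ones(4), np.arange(4.0)
        assert euclidean_distance(a, b) == euclidean_distance(b, a)
        with pytest.raises(ValueError):
            euclidean_distance(np.ones(3), np.ones(4))


class TestTripletLoss:
    @pytest.mark.parametrize(
        "d_ap,d_an,margin,expected",
        [(0.2, 1.0, 0.5, 0.0), (0.8, 0.6, 0.5, 0.7), (0.4, 0.4, 0.5, 0.5)],
    )
    def test_analytic_cases(self, d_ap, d_an, margin, expected):
        assert triplet_loss(d_ap, d_an, margin) == pytest.approx(expected)

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 5, size=(10_000, 2))
        assert all(triplet_loss(a, b, 1.5) >= 0 for a, b in d)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            triplet_loss(0.1, 0.2, margin=0.0)
        with pytest.raises(ValueError):
            triplet_loss(-0.1, 0.2, 1.0)


class TestSampleTriplets:
    def test_enumeration_on_minimal_inventory(self):
        """2 rest + 1 fatigue: anchors must be rest, (A,P) the 2 rest ordered pairs."""
        labels = [REST, REST, FATIGUE]
        pids = ["p", "p", "p"]
        trips = sample_triplets(labels, pids, 500, rng=0)
        seen = {(t.anchor, t.positive, t.negative) for t in trips}
        assert seen == {(0, 1, 2), (1, 0, 2)}
        assert all(t.anchor_class == REST for t in trips)

    def test_constraints_hold_over_many_draws(self):
        rng = np.random.default_rng(1)
        labels = np.array([REST, REST, FATIGUE, FATIGUE] * 5)
        pids = np.repeat([f"p{i}" for i in range(5)], 4)
        trips = sample_triplets(labels, pids, 10_000, rng=rng)
        for t in trips:
            assert pids[t.anchor] == pids[t.positive] == pids[t.negative] == t.participant_id
            assert labels[t.anchor] == labels[t.positive]
            assert labels[t.anchor] != labels[t.negative]
            assert t.anchor != t.positive

    def test_seeded_stream_reproducible(self):
        labels = [REST, REST, FATIGUE, FATIGUE]
        pids = ["p"] * 4
        a = sample_triplets(labels, pids, 50, rng=7)
        b = sample_triplets(labels, pids, 50, rng=7)
        assert a == b

    def test_no_eligible_participant_reports_counts(self):
        with pytest.raises(ValueError, match="counts"):
            sample_triplets([REST, FATIGUE], ["p", "p"], 1, rng=0)


def _separable_embeddings(rng, n_pid=4, per_class=10, gap=3.0):
    V, labels, pids = [], [], []
    for i in range(n_pid):
        base = rng.standard_normal(16)
        for lab, offset in ((REST, 0.0), (FATIGUE, gap)):
            for _ in range(per_class):
                V.append(base + rng.standard_normal(16) * 0.3 + offset)
                labels.append(lab)
                pids.append(f"p{i}")
    return np.array(V), np.array(labels), np.array(pids)


class TestFatigueMetricHead:
    def test_training_separates_classes(self):
        rng = np.random.default_rng(0)
        V, labels, pids = _separable_embeddings(rng)
        head = FatigueMetricHead(SMALL_CFG).fit(V, labels, participants=pids)
        G = head.transform(V)
        d = np.sqrt(((G[:, None] - G[None]) ** 2).sum(-1))
        same = labels[:, None] == labels[None]
        off = ~np.eye(len(labels), dtype=bool)
        assert d[same & off].mean() < d[~same].mean()
        assert len(head.history_) == SMALL_CFG.epochs

    def test_null_separation_loss_approaches_margin(self):
        """With no class structure the triplet loss cannot beat the margin."""
        rng = np.random.default_rng(1)
        V, labels, pids = _separable_embeddings(rng, gap=0.0)
        head = FatigueMetricHead(SMALL_CFG).fit(V, labels, participants=pids)
        assert head.history_[-1] == pytest.approx(SMALL_CFG.margin, rel=0.15)

    def test_refit_reproducible(self):
        rng = np.random.default_rng(2)
        V, labels, pids = _separable_embeddings(rng, n_pid=2, per_class=4)
        h1 = FatigueMetricHead(SMALL_CFG).fit(V, labels, participants=pids)
        h2 = FatigueMetricHead(SMALL_CFG).fit(V, labels, participants=pids)
        assert h1.checksum() == h2.checksum()


class TestSoftmaxHead:
    def test_probabilities_normalised(self):
        rng = np.random.default_rng(3)
        V, labels, _ = _separable_embeddings(rng, n_pid=2)
        head = SoftmaxFatigueHead(SMALL_CFG).fit(V, labels)
        P = head.predict_proba(V)
        assert np.all((P >= 0) & (P <= 1))
        np.testing.assert_allclose(P.sum(axis=1), 1.0)
        assert set(head.predict(V)) <= {REST, FATIGUE}


class TestFrozenBackboneAndLOO:
    def test_train_head_keeps_backbone_frozen(self, pretrained_backbone, tiny_cohort_windows):
        before = pretrained_backbone.checksum()
        tf.train_fatigue_head(pretrained_backbone, tiny_cohort_windows, SMALL_CFG)
        assert pretrained_backbone.checksum() == before

    def test_loo_fold_structure(self, pretrained_backbone, tiny_cohort_windows):
        folds = loo_protocol(tiny_cohort_windows, pretrained_backbone, SMALL_CFG)
        pids = {w.participant_id for w in tiny_cohort_windows}
        assert {f.participant_id for f in folds} == pids
        for f in folds:
            n_heldout = sum(w.participant_id == f.participant_id for w in tiny_cohort_windows)
            assert len(f.heldout_labels) == n_heldout

    def test_loo_order_invariance(self, pretrained_backbone, tiny_cohort_windows):
        rng = np.random.default_rng(0)
        shuffled = [tiny_cohort_windows[i] for i in rng.permutation(len(tiny_cohort_windows))]
        f1 = loo_protocol(tiny_cohort_windows, pretrained_backbone, SMALL_CFG)
        f2 = loo_protocol(shuffled, pretrained_backbone, SMALL_CFG)
        for a, b in zip(f1, f2):
            assert a.participant_id == b.participant_id
            assert a.head.checksum() == b.head.checksum()

    def test_two_participant_cohort(self, pretrained_backbone):
        corpus = tf.simulate_supervised_cohort(n_participants=2, session_minutes=2.0, seed=5)
        windows = tf.featurize_sessions(corpus.sessions)
        folds = loo_protocol(windows, pretrained_backbone, SMALL_CFG)
        assert len(folds) == 2

    def test_single_participant_rejected(self, pretrained_backbone, tiny_cohort_windows):
        one = [w for w in tiny_cohort_windows if w.participant_id == tiny_cohort_windows[0].participant_id]
        with pytest.raises(ValueError):
            loo_protocol(one, pretrained_backbone, SMALL_CFG)
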