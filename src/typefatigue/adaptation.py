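"""Fatigue adaptation over a frozen typing embedding.

The backbone embedding v(x) was learned for *identity*; a single dense
layer with relu activation (the fatigue detection layer) is trained on top
of it, transforming v(x) into g(v(x)) — a space in which rest and fatigue
samples of the same person separate.  Training minimises a triplet hinge
loss over (anchor, positive, negative) triples drawn *within participant*:
anchor and positive share a state, the negative is the other state, so the
head learns state structure while identity variation cancels out.

The backbone is frozen throughout: heads consume precomputed embeddings
and never touch backbone weights (asserted via parameter checksums in
:func:`loo_protocol`).  Evaluation follows a leave-one-participant-out
protocol so every score is subject-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import _nn
from .sessions import FATIGUE, REST, FeatureMatrix


def euclidean_distance(e1: np.ndarray, e2: np.ndarray) -> float:
    """Plain Euclidean distance between two embedding vectors."""
    e1, e2 = np.asarray(e1, float), np.asarray(e2, float)
    if e1.shape != e2.shape:
        raise ValueError(f"dimension mismatch: {e1.shape} vs {e2.shape}")
    return float(np.linalg.norm(e1 - e2))


def triplet_loss(d_ap: float, d_an: float, margin: float = 1.5) -> float:
    """Hinge triplet loss max(0, d_AP - d_AN + margin) on scalar distances."""
    if margin <= 0:
        raise ValueError("margin must be positive")
    if d_ap < 0 or d_an < 0:
        raise ValueError("distances must be nonnegative")
    return max(0.0, d_ap - d_an + margin)


@dataclass(frozen=True)
class Triplet:
    """Index triple (anchor, positive, negative) within one participant."""

    anchor: int
    positive: int
    negative: int
    participant_id: str
    anchor_class: str


@dataclass
class AdaptationConfig:
    """Hyperparameters of the fatigue detection layer and its training."""

    units: int = 128
    margin: float = 1.5
    learning_rate: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    epochs: int = 30
    batches_per_epoch: int = 100
    triplets_per_batch: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")


class _TripletSampler:
    """Uniform within-participant triplet sampler over sample indices.

    A participant is eligible if one state has >= 2 samples and the other
    >= 1.  Per triplet: uniform eligible participant, uniform eligible
    anchor class for them, distinct uniform (anchor, positive) from that
    class, uniform negative from the other class.  Drawing is vectorised
    per (participant, class) entry so large batch schedules stay cheap.
    """

    def __init__(self, labels: np.ndarray, participants: np.ndarray):
        labels = np.asarray(labels)
        participants = np.asarray(participants)
        unknown = set(np.unique(labels)) - {REST, FATIGUE}
        if unknown:
            raise ValueError(f"labels must be rest/fatigue, got extra {sorted(unknown)}")
        self.entries: list[tuple[str, str, np.ndarray, np.ndarray]] = []
        probs = []
        counts = {}
        pids = np.unique(participants)
        for pid in pids:
            sel = participants == pid
            by = {lab: np.flatnonzero(sel & (labels == lab)) for lab in (REST, FATIGUE)}
            counts[str(pid)] = {c: len(ix) for c, ix in by.items()}
            classes = [
                (c, o)
                for c, o in ((REST, FATIGUE), (FATIGUE, REST))
                if len(by[c]) >= 2 and len(by[o]) >= 1
            ]
            for c, o in classes:
                self.entries.append((str(pid), c, by[c], by[o]))
                probs.append(1.0 / (len(pids) * len(classes)))
        if not self.entries:
            raise ValueError(f"no participant eligible for triplet sampling; counts: {counts}")
        p = np.array(probs)
        self.probs = p / p.sum()  # renormalise over eligible participants

    def sample(self, n: int, rng: np.random.Generator):
        """(anchor, positive, negative, entry_index) index arrays of length n."""
        a = np.empty(n, dtype=int)
        p = np.empty(n, dtype=int)
        ng = np.empty(n, dtype=int)
        which = rng.choice(len(self.entries), size=n, p=self.probs)
        for e in np.unique(which):
            sel = np.flatnonzero(which == e)
            _, _, pool, npool = self.entries[e]
            ai = rng.integers(len(pool), size=len(sel))
            pi = rng.integers(len(pool) - 1, size=len(sel))
            pi += pi >= ai  # distinct positive, uniform over the rest
            a[sel] = pool[ai]
            p[sel] = pool[pi]
            ng[sel] = npool[rng.integers(len(npool), size=len(sel))]
        return a, p, ng, which


def sample_triplets(
    labels: Sequence[str],
    participants: Sequence[str],
    n_triplets: int,
    rng: Union[int, np.random.Generator, None] = None,
) -> list[Triplet]:
    """Draw uniform within-participant triplets (see :class:`_TripletSampler`)."""
    labels = np.asarray(labels)
    participants = np.asarray(participants)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sampler = _TripletSampler(labels, participants)
    a, p, n, which = sampler.sample(n_triplets, rng)
    return [
        Triplet(int(ai), int(pi), int(ni), sampler.entries[w][0], sampler.entries[w][1])
        for ai, pi, ni, w in zip(a, p, n, which)
    ]


class FatigueMetricHead(BaseEstimator, TransformerMixin):
    """Dense relu fatigue detection layer trained with the triplet loss.

    ``fit(V, y, participants=...)`` consumes precomputed backbone
    embeddings ``V`` (n, d) with state labels ``y`` in {rest, fatigue} and
    participant ids; ``transform`` maps embeddings into the fatigue space
    g(v(x)).  The backbone itself is never seen, hence trivially frozen.
    """

    def __init__(self, config: Optional[AdaptationConfig] = None, random_state: Optional[int] = None):
        self.config = config
        self.random_state = random_state

    def _resolved(self) -> AdaptationConfig:
        cfg = self.config or AdaptationConfig()
        if self.random_state is not None:
            cfg = AdaptationConfig(**{**cfg.__dict__, "seed": self.random_state})
        return cfg

    def fit(self, V, y, participants=None) -> "FatigueMetricHead":
        V = np.asarray(V, float)
        y = np.asarray(y)
        if participants is None:
            participants = np.zeros(len(y), dtype=object)
        participants = np.asarray(participants)
        cfg = self._resolved()
        rng = np.random.default_rng(cfg.seed)
        sampler = _TripletSampler(y, participants)
        self.params_ = _nn.init_dense_params(rng, V.shape[1], cfg.units)
        opt = _nn.Adam(cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps)
        self.history_ = []
        for _epoch in range(cfg.epochs):
            losses = []
            for _b in range(cfg.batches_per_epoch):
                a, p, n, _ = sampler.sample(cfg.triplets_per_batch, rng)
                sel = np.concatenate([a, p, n])
                G, cache = _nn.dense_forward(self.params_, V[sel], relu=True)
                loss, dG, _ = _nn.triplet_hinge(G, cfg.margin)
                _, grads = _nn.dense_backward(cache, dG)
                opt.step(self.params_, grads)
                losses.append(loss)
            self.history_.append(float(np.mean(losses)))
        return self

    def transform(self, V) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise NotFittedError("FatigueMetricHead is not fitted")
        G, _ = _nn.dense_forward(self.params_, np.asarray(V, float), relu=True)
        return G

    def checksum(self) -> float:
        return _nn.params_checksum(self.params_)


class SoftmaxFatigueHead(BaseEstimator, ClassifierMixin):
    """Binary softmax baseline head (relu layer + softmax, cross-entropy).

    Same frozen-backbone regime as the metric head but trained as a plain
    binary classifier; used only as a comparison arm.
    """

    def __init__(self, config: Optional[AdaptationConfig] = None, random_state: Optional[int] = None):
        self.config = config
        self.random_state = random_state

    def fit(self, V, y) -> "SoftmaxFatigueHead":
        V = np.asarray(V, float)
        y = np.asarray(y)
        self.classes_ = np.array([REST, FATIGUE])
        yi = (y == FATIGUE).astype(int)
        cfg = FatigueMetricHead(self.config, self.random_state)._resolved()
        rng = np.random.default_rng(cfg.seed)
        self.params_ = {
            "hidden": _nn.init_dense_params(rng, V.shape[1], cfg.units),
            "out": _nn.init_dense_params(rng, cfg.units, 2),
        }
        opt_hid = _nn.Adam(cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps)
        opt_out = _nn.Adam(cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.eps)
        self.history_ = []
        bs = cfg.triplets_per_batch
        for _epoch in range(cfg.epochs):
            losses = []
            for _b in range(cfg.batches_per_epoch):
                sel = rng.integers(len(yi), size=bs)
                H, ch = _nn.dense_forward(self.params_["hidden"], V[sel], relu=True)
                Z, cz = _nn.dense_forward(self.params_["out"], H, relu=False)
                loss, dZ, _ = _nn.softmax_xent(Z, yi[sel])
                dH, g_out = _nn.dense_backward(cz, dZ)
                _, g_hid = _nn.dense_backward(ch, dH)
                opt_hid.step(self.params_["hidden"], g_hid)
                opt_out.step(self.params_["out"], g_out)
                losses.append(loss)
            self.history_.append(float(np.mean(losses)))
        return self

    def predict_proba(self, V) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise NotFittedError("SoftmaxFatigueHead is not fitted")
        H, _ = _nn.dense_forward(self.params_["hidden"], np.asarray(V, float), relu=True)
        Z, _ = _nn.dense_forward(self.params_["out"], H, relu=False)
        z = Z - Z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict(self, V) -> np.ndarray:
        return self.classes_[self.predict_proba(V).argmax(axis=1)]

    def checksum(self) -> float:
        return _nn.params_checksum(self.params_)


def train_fatigue_head(
    backbone,
    windows: Sequence[FeatureMatrix],
    config: Optional[AdaptationConfig] = None,
    kind: str = "dml",
):
    """Embed windows with the frozen backbone and train a head on top.

    Returns the fitted head; raises if the backbone's parameters change
    during training (frozen contract).
    """
    labels = np.array([w.label for w in windows])
    pids = np.array([w.participant_id for w in windows])
    before = backbone.checksum()
    V = backbone.transform(windows)
    if kind == "dml":
        head = FatigueMetricHead(config).fit(V, labels, participants=pids)
    elif kind == "softmax":
        head = SoftmaxFatigueHead(config).fit(V, labels)
    else:
        raise ValueError(f"unknown head kind {kind!r}")
    after = backbone.checksum()
    if before != after:
        raise AssertionError("frozen-backbone contract violated: backbone weights changed")
    return head


@dataclass
class LOOFold:
    """One leave-one-participant-out fold result."""

    participant_id: str
    head: object
    heldout_embeddings: np.ndarray  # g(v(x)) of the held-out participant
    heldout_labels: np.ndarray
    train_rest_embeddings: np.ndarray = field(default=None)
    train_fatigue_embeddings: np.ndarray = field(default=None)


def loo_protocol(
    windows: Sequence[FeatureMatrix],
    backbone,
    config: Optional[AdaptationConfig] = None,
    kind: str = "dml",
) -> list[LOOFold]:
    """Leave-one-participant-out adaptation.

    For each participant, a head is trained on all *other* participants'
    windows (triplet sampling never sees the held-out person — leakage is
    asserted) and the held-out windows are mapped into the fatigue space.
    Fold order and contents are deterministic given the config seed,
    independent of input ordering.
    """
    labels = np.array([w.label for w in windows])
    pids = np.array([w.participant_id for w in windows])
    if len(np.unique(pids)) < 2:
        raise ValueError("LOO protocol needs at least 2 participants")
    before = backbone.checksum()
    V = backbone.transform(windows)
    # canonical ordering (participant, label, content digest) so fold training
    # streams are invariant to how the caller ordered the windows
    import hashlib

    digests = np.array(
        [hashlib.md5(np.ascontiguousarray(w.values).tobytes()).hexdigest() for w in windows]
    )
    order = np.lexsort((digests, labels, pids))
    V, labels, pids = V[order], labels[order], pids[order]
    folds = []
    for pid in np.unique(pids):
        test = pids == pid
        train = ~test
        assert not np.any(pids[train] == pid), "participant leakage into training fold"
        if kind == "dml":
            head = FatigueMetricHead(config).fit(
                V[train], labels[train], participants=pids[train]
            )
            G_test = head.transform(V[test])
            G_train = head.transform(V[train])
        else:
            head = SoftmaxFatigueHead(config).fit(V[train], labels[train])
            G_test = head.predict_proba(V[test])[:, 1:]  # fatigue probability as 1-d "embedding"
            G_train = head.predict_proba(V[train])[:, 1:]
        folds.append(
            LOOFold(
                participant_id=str(pid),
                head=head,
                heldout_embeddings=G_test,
                heldout_labels=labels[test],
                train_rest_embeddings=G_train[labels[train] == REST],
                train_fatigue_embeddings=G_train[labels[train] == FATIGUE],
            )
        )
    if backbone.checksum() != before:
        raise AssertionError("frozen-backbone contract violated during LOO")
    return folds
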