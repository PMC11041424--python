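"""Recurrent typing-pattern embedding backbone.

A two-layer masked LSTM maps a 150x4 keystroke timing matrix to a 128-d
embedding v(x) in which sequences typed by the same person cluster.  The
backbone is pretrained on *identity* (who typed the sequence) with the same
triplet machinery later used for fatigue adaptation; downstream the
backbone is frozen and only a small head is trained on top of v(x).

The embedding is the hidden state of the last recurrent layer at the final
valid (non-padded) timestep; the masking contract guarantees trailing zero
padding never influences it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import _nn
from .sessions import N_FEATURES, WINDOW_KEYS, FeatureMatrix, stack_features

_CLIP_NORM = 5.0  # global gradient-norm clip for recurrent training stability


@dataclass
class BackboneConfig:
    """Architecture of the recurrent embedding network."""

    n_recurrent_layers: int = 2
    units_per_layer: int = 128
    recurrent_dropout: float = 0.2
    inter_layer_dropout: float = 0.5
    input_shape: tuple[int, int] = (WINDOW_KEYS, N_FEATURES)
    embedding_dim: int = 128
    mask_padded_rows: bool = True

    def __post_init__(self) -> None:
        if self.embedding_dim != self.units_per_layer:
            raise ValueError("embedding_dim must equal units of the last recurrent layer")
        if not self.mask_padded_rows:
            raise ValueError("masking must stay on when zero padding is used")
        if self.n_recurrent_layers != 2:
            raise ValueError("backbone is defined with exactly 2 recurrent layers")


def _as_batch(X) -> tuple[np.ndarray, np.ndarray]:
    """Coerce input to (values (n, T, 4), lengths (n,)).

    Accepts a sequence of FeatureMatrix (preferred; exact valid lengths) or
    a raw (n, T, 4) array, in which case the valid length of each sample is
    inferred as one past its last non-zero row (zero rows are padding).
    """
    if len(X) > 0 and isinstance(X[0], FeatureMatrix):
        return stack_features(X)
    x = np.asarray(X, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[2] != N_FEATURES:
        raise ValueError(f"expected (n, T, {N_FEATURES}) input, got {x.shape}")
    nonzero = np.any(x != 0.0, axis=2)
    lengths = np.where(
        nonzero.any(axis=1), x.shape[1] - np.argmax(nonzero[:, ::-1], axis=1), 1
    )
    return x, lengths.astype(np.int64)


class TypingEmbedder(BaseEstimator, TransformerMixin):
    """Two-layer masked LSTM typing embedder with triplet pretraining.

    Parameters
    ----------
    units : int
        Hidden units per recurrent layer; also the embedding dimension.
    recurrent_dropout, inter_layer_dropout : float
        Dropout rates used only during training (inference is deterministic).
    margin : float
        Triplet hinge margin for identity pretraining.  The loss acts on
        batch-centred, unit-normalised embeddings, so the margin lives on
        the unit hypersphere; 0.2 is the customary value at that scale.
    learning_rate, epochs, batches_per_epoch, triplets_per_batch :
        Adam/optimisation schedule for :meth:`fit`.
    random_state : int
        Seeds weight initialisation, dropout and triplet sampling.

    Attributes
    ----------
    weights_ : dict
        Flat parameter dict (``lstm1.W`` etc.) after :meth:`initialize`,
        :meth:`fit` or :meth:`load`.
    history_ : list of float
        Deterministic triplet loss on a fixed evaluation set, before
        training and after each epoch (length ``epochs + 1``).
    train_history_ : list of float
        Mean (dropout-active) training-batch loss per epoch.
    """

    def __init__(
        self,
        units: int = 128,
        recurrent_dropout: float = 0.2,
        inter_layer_dropout: float = 0.5,
        margin: float = 0.2,
        learning_rate: float = 3e-4,
        epochs: int = 4,
        batches_per_epoch: int = 12,
        triplets_per_batch: int = 48,
        random_state: Optional[int] = 0,
    ):
        self.units = units
        self.recurrent_dropout = recurrent_dropout
        self.inter_layer_dropout = inter_layer_dropout
        self.margin = margin
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batches_per_epoch = batches_per_epoch
        self.triplets_per_batch = triplets_per_batch
        self.random_state = random_state

    # -- construction -----------------------------------------------------

    @property
    def config(self) -> BackboneConfig:
        return BackboneConfig(
            units_per_layer=self.units,
            recurrent_dropout=self.recurrent_dropout,
            inter_layer_dropout=self.inter_layer_dropout,
            embedding_dim=self.units,
        )

    def initialize(self) -> "TypingEmbedder":
        """Create seeded random weights without training."""
        rng = np.random.default_rng(self.random_state)
        l1 = _nn.init_lstm_params(rng, N_FEATURES, self.units)
        l2 = _nn.init_lstm_params(rng, self.units, self.units)
        self.weights_ = {f"lstm1.{k}": v for k, v in l1.items()}
        self.weights_.update({f"lstm2.{k}": v for k, v in l2.items()})
        self.history_ = []
        return self

    def _layer(self, prefix: str) -> dict:
        return {k: self.weights_[f"{prefix}.{k}"] for k in ("W", "U", "b")}

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise NotFittedError("TypingEmbedder has no weights; call fit/initialize/load first")

    def checksum(self) -> float:
        """Scalar fingerprint of all backbone parameters (frozen contract)."""
        self._check_fitted()
        return _nn.params_checksum(self.weights_)

    # -- forward ----------------------------------------------------------

    def _forward(self, x: np.ndarray, lengths: np.ndarray, rng=None):
        """Forward pass; with `rng`, dropout is active (training mode)."""
        Tmax = int(lengths.max())
        x = x[:, :Tmax]
        mask = (np.arange(Tmax)[None, :] < lengths[:, None]).astype(np.float64)
        B = x.shape[0]
        if rng is not None and self.recurrent_dropout > 0:
            p = self.recurrent_dropout
            rd1 = (rng.uniform(size=(B, self.units)) >= p) / (1 - p)
            rd2 = (rng.uniform(size=(B, self.units)) >= p) / (1 - p)
        else:
            rd1 = rd2 = None
        H1, c1 = _nn.lstm_forward(self._layer("lstm1"), x, mask, rd1)
        if rng is not None and self.inter_layer_dropout > 0:
            p = self.inter_layer_dropout
            dmask = (rng.uniform(size=H1.shape) >= p) / (1 - p)
            H1d = H1 * dmask
        else:
            dmask = None
            H1d = H1
        H2, c2 = _nn.lstm_forward(self._layer("lstm2"), H1d, mask, rd2)
        emb = H2[:, -1]
        return emb, (c1, c2, dmask)

    def _backward(self, caches, dEmb: np.ndarray) -> dict:
        c1, c2, dmask = caches
        dH1d, g2 = _nn.lstm_backward(c2, dHs=None, dh_last=dEmb)
        if dmask is not None:
            dH1d = dH1d * dmask
        _, g1 = _nn.lstm_backward(c1, dHs=dH1d)
        grads = {f"lstm1.{k}": v for k, v in g1.items()}
        grads.update({f"lstm2.{k}": v for k, v in g2.items()})
        return grads

    def transform(self, X, batch_size: int = 256) -> np.ndarray:
        """Embed samples; deterministic (dropout off). Returns (n, units)."""
        self._check_fitted()
        x, lengths = _as_batch(X)
        out = np.empty((x.shape[0], self.units))
        for s in range(0, x.shape[0], batch_size):
            sl = slice(s, s + batch_size)
            out[sl] = self._forward(x[sl], lengths[sl])[0]
        return out

    embed = transform

    # -- identity pretraining --------------------------------------------

    def fit(self, X, y) -> "TypingEmbedder":
        """Pretrain on identity labels with the triplet hinge loss.

        ``X``: sequence of FeatureMatrix or (n, T, 4) array; ``y``: typist
        identity per sample.  Requires >= 2 identities with >= 2 samples.
        """
        x, lengths = _as_batch(X)
        y = np.asarray(y)
        ids, inv = np.unique(y, return_inverse=True)
        by_user = [np.flatnonzero(inv == u) for u in range(len(ids))]
        eligible = [u for u, idx in enumerate(by_user) if len(idx) >= 2]
        if len(ids) < 2 or len(eligible) < 1:
            raise ValueError(
                f"identity pretraining needs >= 2 users and an anchor user with >= 2 "
                f"sessions; got {len(ids)} user(s)"
            )
        rng = np.random.default_rng(self.random_state)
        self.initialize()
        opt = _nn.Adam(lr=self.learning_rate)

        def draw_triplets(n):
            au = rng.choice(eligible, size=n)
            a_idx = np.empty(n, dtype=int)
            p_idx = np.empty(n, dtype=int)
            n_idx = np.empty(n, dtype=int)
            for j, u in enumerate(au):
                a, p = rng.choice(by_user[u], size=2, replace=False)
                others = rng.integers(len(ids) - 1)
                v = others + (others >= u)  # uniform over users != u
                a_idx[j], p_idx[j] = a, p
                n_idx[j] = rng.choice(by_user[v])
            return np.concatenate([a_idx, p_idx, n_idx])

        # fixed evaluation triplets: deterministic (dropout-free) loss curve
        eval_sel = draw_triplets(min(256, 8 * self.triplets_per_batch))

        def eval_loss() -> float:
            emb = self._forward(x[eval_sel], lengths[eval_sel])[0]
            return _nn.triplet_hinge(_nn.standardize_forward(emb)[0], self.margin)[0]

        self.history_ = [eval_loss()]
        self.train_history_ = []
        for _epoch in range(self.epochs):
            epoch_losses = []
            for _batch in range(self.batches_per_epoch):
                sel = draw_triplets(self.triplets_per_batch)
                emb, caches = self._forward(x[sel], lengths[sel], rng=rng)
                # loss on batch-standardised embeddings: no reward for global
                # shrinkage or common-mode drift (both collapse the raw hinge)
                normed, ncache = _nn.standardize_forward(emb)
                loss, dN, _ = _nn.triplet_hinge(normed, self.margin)
                dE = _nn.standardize_backward(ncache, dN)
                grads = self._backward(caches, dE)
                _clip_grads(grads)
                opt.step(self.weights_, grads)
                epoch_losses.append(loss)
            self.train_history_.append(float(np.mean(epoch_losses)))
            self.history_.append(eval_loss())
        return self

    def identity_separation(self, X, y) -> dict:
        """Mean intra- vs inter-user embedding distance on given samples."""
        emb = self.transform(X)
        y = np.asarray(y)
        d = np.sqrt(((emb[:, None] - emb[None]) ** 2).sum(-1))
        same = y[:, None] == y[None]
        off = ~np.eye(len(y), dtype=bool)
        return {
            "intra": float(d[same & off].mean()),
            "inter": float(d[~same].mean()),
        }

    # -- persistence ------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        """Weights to ``.npz`` plus a JSON sidecar with config and seed."""
        self._check_fitted()
        path = Path(path)
        np.savez(path, **self.weights_)
        sidecar = {
            "config": asdict(self.config),
            "params": self.get_params(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TypingEmbedder":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        est = cls(**sidecar["params"])
        with np.load(path) as f:
            est.weights_ = {k: f[k].copy() for k in f.files}
        est.history_ = []
        expected = (N_FEATURES, 4 * est.units)
        got = est.weights_["lstm1.W"].shape
        if got != expected:
            raise ValueError(
                f"weight file incompatible with config: lstm1.W is {got}, expected {expected}"
            )
        return est

    def load_weights(self, path: Union[str, Path]) -> "TypingEmbedder":
        """Load weights into *this* estimator, validating shapes against config."""
        other = type(self).load(path)
        if other.units != self.units:
            raise ValueError(
                f"checkpoint has {other.units}-unit layers, config asks for {self.units}"
            )
        self.weights_ = other.weights_
        self.history_ = []
        return self


def _clip_grads(grads: dict, max_norm: float = _CLIP_NORM) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def build_backbone(config: Optional[BackboneConfig] = None, seed: int = 0) -> TypingEmbedder:
    """Seeded, randomly initialised embedder (no pretraining)."""
    config = config or BackboneConfig()
    return TypingEmbedder(
        units=config.units_per_layer,
        recurrent_dropout=config.recurrent_dropout,
        inter_layer_dropout=config.inter_layer_dropout,
        random_state=seed,
    ).initialize()


def pretrain_backbone(corpus, seed: int = 0, **hyper) -> TypingEmbedder:
    """Pretrain an embedder on a simulated identity corpus.

    ``corpus`` is a :class:`~typefatigue.simulate.SimulatedCorpus`; each
    session becomes one (head-truncated) window labelled with its typist.
    """
    from .io import segment_session

    X, y = [], []
    for s in corpus.sessions:
        X.append(segment_session(s, policy="first_only")[0])
        y.append(s.participant_id)
    est = TypingEmbedder(random_state=seed, **hyper)
    return est.fit(X, np.asarray(y))
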