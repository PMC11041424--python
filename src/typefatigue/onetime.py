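"""Onetime (pairwise) fatigue change detection and its evaluation.

A *change score* for a pair of same-participant samples is the Euclidean
distance between their fatigue-space embeddings: a distance above threshold
signals a state change (rest->fatigue or fatigue->rest), below it no
change.  This module builds intra-participant pair pools from LOO fold
outputs, runs the ROC analysis (pooled or per-participant averaged), picks
the closest-to-(0,1)-corner operating point, and provides the statistical
baseline classifiers (random forest, RBF-kernel SVM, k-NN on per-sample
summary statistics of the timing features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .adaptation import LOOFold
from .io import segment_session, segment_session_by_time
from .sessions import FATIGUE, REST, KeystrokeSession

CHANGE = "change"
NO_CHANGE = "no_change"


@dataclass(frozen=True)
class ChangeScorePair:
    """One intra-participant sample pair with its distance score."""

    participant_id: str
    distance: float
    truth: str  # change / no_change
    setup_tag: str = "150keys"


@dataclass
class DetectionReport:
    """ROC summary plus operating-point metrics, rates in percent."""

    auc_percent: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    aggregation: str = "pooled"
    extra: dict = field(default_factory=dict)


def build_pairs(
    folds: Sequence[LOOFold],
    policy: str = "balanced",
    max_pairs_per_class: int = 50,
    rng: Union[int, np.random.Generator, None] = None,
    setup_tag: str = "150keys",
) -> list[ChangeScorePair]:
    """Intra-participant pairs of held-out fatigue-space embeddings.

    All unordered pairs are enumerated per participant; under the
    ``balanced`` policy each participant contributes at most
    ``max_pairs_per_class`` change and no-change pairs (subsampled without
    replacement).  ``all`` keeps every pair.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pairs: list[ChangeScorePair] = []
    for fold in folds:
        G = fold.heldout_embeddings
        labels = fold.heldout_labels
        n = len(labels)
        if n < 2:
            continue
        iu, ju = np.triu_indices(n, k=1)
        d = np.linalg.norm(G[iu] - G[ju], axis=1)
        change = labels[iu] != labels[ju]
        for is_change in (False, True):
            sel = np.flatnonzero(change == is_change)
            if policy == "balanced" and len(sel) > max_pairs_per_class:
                sel = rng.choice(sel, size=max_pairs_per_class, replace=False)
            for k in sel:
                pairs.append(
                    ChangeScorePair(
                        participant_id=fold.participant_id,
                        distance=float(d[k]),
                        truth=CHANGE if is_change else NO_CHANGE,
                        setup_tag=setup_tag,
                    )
                )
    return pairs


def _pairs_arrays(pairs: Sequence[ChangeScorePair]):
    y = np.array([p.truth == CHANGE for p in pairs], dtype=int)
    s = np.array([p.distance for p in pairs])
    pid = np.array([p.participant_id for p in pairs])
    return y, s, pid


def operating_point(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray,
                    y: np.ndarray, scores: np.ndarray) -> dict:
    """Closest-to-(0,1)-corner cutoff and the metrics computed there.

    Ties in corner distance break toward higher TPR.  Metrics are computed
    on the given scores at the selected cutoff (predict change when
    score >= cutoff, the ROC-point convention), in percent.
    """
    corner = fpr**2 + (1.0 - tpr) ** 2
    best = np.flatnonzero(corner == corner.min())
    idx = best[np.argmax(tpr[best])]
    cut = thresholds[idx]
    pred = scores >= cut
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    sens = 100.0 * tp / max(tp + fn, 1)
    spec = 100.0 * tn / max(tn + fp, 1)
    prec = 100.0 * tp / max(tp + fp, 1)
    f1 = 2 * prec * sens / max(prec + sens, 1e-12)
    return {
        "cutoff": float(cut),
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
    }


def roc_analysis(
    pairs_or_scores,
    aggregation: str = "pooled",
    fpr_grid: Optional[np.ndarray] = None,
) -> DetectionReport:
    """ROC/AUC analysis of change scores.

    ``pooled`` treats all cross-validated scores as one prediction set;
    ``per_participant_averaged`` computes one ROC per participant and
    vertically averages TPR on a common FPR grid (AUC by trapezoid).
    Input: a list of :class:`ChangeScorePair`, or a tuple
    ``(y_change, scores[, participant_ids])``.
    """
    if isinstance(pairs_or_scores, tuple):
        y, s = pairs_or_scores[0], pairs_or_scores[1]
        y, s = np.asarray(y, int), np.asarray(s, float)
        pid = (
            np.asarray(pairs_or_scores[2])
            if len(pairs_or_scores) > 2
            else np.zeros(len(y), dtype=object)
        )
    else:
        y, s, pid = _pairs_arrays(pairs_or_scores)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC analysis needs both change and no-change pairs")

    fpr_p, tpr_p, thr_p = roc_curve(y, s)
    op = operating_point(fpr_p, tpr_p, thr_p, y, s)

    if aggregation == "pooled":
        auc_val = roc_auc_score(y, s)
        fpr, tpr = fpr_p, tpr_p
    elif aggregation == "per_participant_averaged":
        grid = fpr_grid if fpr_grid is not None else np.linspace(0.0, 1.0, 201)
        curves = []
        for p in np.unique(pid):
            sel = pid == p
            if len(np.unique(y[sel])) < 2:
                continue
            f, t, _ = roc_curve(y[sel], s[sel])
            curves.append(np.interp(grid, f, t))
        if not curves:
            raise ValueError("no participant has both pair classes")
        tpr = np.mean(curves, axis=0)
        fpr = grid
        auc_val = _auc(grid, tpr)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    return DetectionReport(
        auc_percent=100.0 * float(auc_val),
        sensitivity=op["sensitivity"],
        specificity=op["specificity"],
        precision=op["precision"],
        f1=op["f1"],
        roc_fpr=np.asarray(fpr),
        roc_tpr=np.asarray(tpr),
        aggregation=aggregation,
        extra={"n_pairs": int(len(y)), "cutoff": op["cutoff"]},
    )


# ---------------------------------------------------------------------------
# statistical-feature baselines

#: summary statistics applied to each timing-feature column
_STATS = ("mean", "median", "sd", "q25", "q75")


def summary_features(matrix: np.ndarray) -> np.ndarray:
    """20-d summary (5 statistics x 4 timing features) of an (L, 4) matrix."""
    m = np.asarray(matrix, float)
    return np.concatenate(
        [
            m.mean(axis=0),
            np.median(m, axis=0),
            m.std(axis=0, ddof=1) if m.shape[0] > 1 else np.zeros(m.shape[1]),
            np.percentile(m, 25, axis=0),
            np.percentile(m, 75, axis=0),
        ]
    )


def _baseline_models(seed: int) -> dict:
    return {
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "svm": make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed)),
        "knn": make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5)),
    }


def baseline_feature_table(
    sessions: Sequence[KeystrokeSession], setup: str = "150keys"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, participants) summary-feature table for the baselines.

    ``150keys``: one sample per nonoverlapping 150-key window; ``5min``:
    one sample per 5-minute span (all keys within, not truncated).
    """
    rows, labels, pids = [], [], []
    for s in sessions:
        if setup == "150keys":
            mats = [w.trimmed() for w in segment_session(s)]
        elif setup == "5min":
            mats = segment_session_by_time(s, window_seconds=300.0)
        else:
            raise ValueError(f"unknown setup {setup!r}")
        for m in mats:
            rows.append(summary_features(m))
            labels.append(s.label)
            pids.append(s.participant_id)
    return np.array(rows), np.array(labels), np.array(pids)


def baseline_classifiers(
    sessions: Sequence[KeystrokeSession], setup: str = "150keys", seed: int = 0
) -> dict[str, DetectionReport]:
    """Subject-wise LOO evaluation of the statistical baselines.

    Each classifier is trained on summary features of all participants but
    one and scores the held-out participant's samples (probability /
    decision value for the fatigue class); held-out scores are pooled into
    one ROC per classifier.
    """
    X, y, pids = baseline_feature_table(sessions, setup)
    ybin = (y == FATIGUE).astype(int)
    reports = {}
    for name, proto in _baseline_models(seed).items():
        scores = np.empty(len(ybin))
        for pid in np.unique(pids):
            test = pids == pid
            if len(np.unique(ybin[~test])) < 2:
                raise ValueError(f"training fold for {pid} has a single class")
            model = clone(proto).fit(X[~test], ybin[~test])
            if hasattr(model, "predict_proba"):
                scores[test] = model.predict_proba(X[test])[:, 1]
            else:
                scores[test] = model.decision_function(X[test])
        reports[name] = roc_analysis((ybin, scores, pids), aggregation="pooled")
        reports[name].extra["setup"] = setup
        reports[name].extra["n_samples"] = int(len(ybin))
    return reports
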