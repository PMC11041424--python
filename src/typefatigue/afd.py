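"""Active fatigue detection: CUSUM quick change detection over session scores.

The fatigue-space embedding g(v(x)) of each incoming keystroke session is
projected to a scalar fatigue score; the log-likelihood ratio of that score
under the fatigue vs rest score densities is accumulated with a clamped
(Page-style) CUSUM,

    S_j = max(0, S_{j-1} + L_j),      L_j = ln f_F(score_j) - ln f_R(score_j),

so the statistic hovers near zero while the typist is rested and climbs
once consecutive sessions look fatigued; crossing a threshold tau raises a
detection.  Sweeping tau yields the probability of false detection (PFD),
probability of nondetection (PND) and average detection delay (ADD)
trade-off curves and the equal error rate (EER) where PFD = PND.

Two scalar projections are provided: a deterministic ``centroid_axis``
(signed projection onto the rest-to-fatigue centroid axis of the training
folds — the default) and a seeded 1-D t-SNE (``tsne1d``), which is
transductive and seed-sensitive.

The module also hosts the real-world daily-trend analysis: per-participant
fatigue scores on consecutive session pairs less than 2 hours apart within
a day, aggregated by hour of day with bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .sessions import KeystrokeSession

DENSITY_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# scalar projection


def project_to_scalar(
    embeddings: np.ndarray,
    method: str = "centroid_axis",
    rest_centroid: Optional[np.ndarray] = None,
    fatigue_centroid: Optional[np.ndarray] = None,
    reference: Optional[np.ndarray] = None,
    random_state: int = 0,
) -> np.ndarray:
    """Reduce fatigue-space embeddings to one scalar score per sample.

    ``centroid_axis``: signed projection onto the unit vector from the
    rest centroid to the fatigue centroid (both from training folds),
    origin at the rest centroid — deterministic and inductive.

    ``tsne1d``: 1-D t-SNE fit jointly on ``reference`` (if given) plus the
    incoming embeddings; returns the coordinates of the incoming block.
    Transductive; reproducible only under a fixed seed.
    """
    E = np.atleast_2d(np.asarray(embeddings, float))
    if method == "centroid_axis":
        if rest_centroid is None or fatigue_centroid is None:
            raise ValueError("centroid_axis needs rest and fatigue centroids")
        cr = np.asarray(rest_centroid, float)
        cf = np.asarray(fatigue_centroid, float)
        axis = cf - cr
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("rest and fatigue centroids coincide; axis undefined")
        return (E - cr) @ (axis / norm)
    if method == "tsne1d":
        from sklearn.manifold import TSNE

        blocks = [np.atleast_2d(reference)] if reference is not None else []
        blocks.append(E)
        Z = np.vstack(blocks)
        if Z.shape[0] < 2:
            raise ValueError("tsne1d needs at least 2 points")
        perplexity = min(30.0, (Z.shape[0] - 1) / 3.0)
        coord = TSNE(
            n_components=1,
            perplexity=max(perplexity, 1.0),
            random_state=random_state,
            init="random",
        ).fit_transform(Z)[:, 0]
        return coord[-E.shape[0] :]
    raise ValueError(f"unknown projection method {method!r}")


# ---------------------------------------------------------------------------
# score densities and the log-likelihood ratio


@dataclass
class ScoreDensities:
    """Gaussian KDEs of rest and fatigue scalar scores, with a floor."""

    f_rest: gaussian_kde
    f_fatigue: gaussian_kde
    floor: float = DENSITY_FLOOR

    def eval_rest(self, s) -> np.ndarray:
        return np.maximum(self.f_rest(np.atleast_1d(s)), self.floor)

    def eval_fatigue(self, s) -> np.ndarray:
        return np.maximum(self.f_fatigue(np.atleast_1d(s)), self.floor)


def estimate_densities(
    rest_scores: np.ndarray,
    fatigue_scores: np.ndarray,
    bandwidth: Union[str, float] = "silverman",
    floor: float = DENSITY_FLOOR,
    min_per_class: int = 5,
) -> ScoreDensities:
    """Gaussian KDEs (Silverman bandwidth by default) of the two classes."""
    r = np.asarray(rest_scores, float).ravel()
    f = np.asarray(fatigue_scores, float).ravel()
    if len(r) < min_per_class or len(f) < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} scores per class (got {len(r)} rest, {len(f)} "
            "fatigue); consider pooling cohort scores"
        )
    if np.ptp(r) == 0 or np.ptp(f) == 0:
        raise ValueError("degenerate (constant) score sample; KDE bandwidth undefined")
    return ScoreDensities(
        gaussian_kde(r, bw_method=bandwidth), gaussian_kde(f, bw_method=bandwidth), floor
    )


def llr(score, densities: ScoreDensities):
    """Log-likelihood ratio ln f_F(score) - ln f_R(score), floored densities.

    Negative for rest-like scores, positive for fatigue-like ones.
    """
    s = np.atleast_1d(np.asarray(score, float))
    out = np.log(densities.eval_fatigue(s)) - np.log(densities.eval_rest(s))
    return float(out[0]) if np.isscalar(score) or np.ndim(score) == 0 else out


# ---------------------------------------------------------------------------
# CUSUM


@dataclass
class AFDState:
    """Running state of the clamped CUSUM detector."""

    tau: float = np.inf
    S: float = 0.0
    j: int = 0
    history: list = field(default_factory=list)  # (score_or_nan, L_j, S_j)

    @property
    def detected(self) -> bool:
        return self.S >= self.tau


def update_cusum(state: AFDState, L_j: float, score_j: float = np.nan) -> AFDState:
    """One clamped-CUSUM step: S_j = max(0, S_{j-1} + L_j), appended to history."""
    state.S = max(0.0, state.S + float(L_j))
    state.j += 1
    state.history.append((float(score_j), float(L_j), state.S))
    return state


def run_cusum(L_seq: Sequence[float], tau: float = np.inf) -> tuple[np.ndarray, Optional[int]]:
    """CUSUM trajectory over a whole LLR sequence.

    Returns (S trajectory, index of first threshold crossing or None).
    """
    state = AFDState(tau=tau)
    for L in L_seq:
        update_cusum(state, L)
    S = np.array([h[2] for h in state.history])
    crossed = np.flatnonzero(S >= tau)
    return S, (int(crossed[0]) if len(crossed) else None)


# ---------------------------------------------------------------------------
# threshold-sweep evaluation


@dataclass
class AFDMetrics:
    """PFD/PND/ADD curves over a threshold grid, plus the EER point."""

    thresholds: np.ndarray
    pfd: np.ndarray
    pnd: np.ndarray
    add: np.ndarray  # censored mean delay (nondetections count the full horizon)
    eer: float
    eer_threshold: float
    add_at_eer: float  # censored mean delay at the EER threshold
    median_add_at_eer: float  # median delay among *detected* sequences at EER


def evaluate_afd(
    sequences: Sequence[tuple[np.ndarray, int]],
    thresholds: Optional[np.ndarray] = None,
    n_thresholds: int = 200,
) -> AFDMetrics:
    """Sweep detection thresholds over LLR sequences with known change points.

    Each element of ``sequences`` is ``(L_seq, change_index)``: the session
    at ``change_index`` is the first fatigued one.  For each threshold tau:
    PFD is the fraction of sequences whose CUSUM crosses tau before the
    change; PND the fraction never crossing at/after it; ADD the mean delay
    (in sessions, first post-change session = 1) with nondetections
    censored at the post-change horizon.  EER is the PFD = PND crossing,
    linearly interpolated on the grid.
    """
    if not sequences:
        raise ValueError("no sequences to evaluate")
    trajs = []
    for L_seq, change in sequences:
        S, _ = run_cusum(L_seq)
        trajs.append((S, int(change)))
    if thresholds is None:
        smax = max(S.max() for S, _ in trajs)
        thresholds = np.linspace(0.0, max(smax, 1e-9) * 1.001, n_thresholds)
    thresholds = np.asarray(thresholds, float)

    n = len(trajs)
    pfd = np.zeros_like(thresholds)
    pnd = np.zeros_like(thresholds)
    add = np.zeros_like(thresholds)
    for k, tau in enumerate(thresholds):
        false_det = 0
        miss = 0
        delays = []
        for S, change in trajs:
            pre = S[:change]
            post = S[change:]
            if len(pre) and pre.max() >= tau:
                false_det += 1
            horizon = len(post)
            crossed = np.flatnonzero(post >= tau)
            if len(crossed):
                delays.append(crossed[0] + 1)  # sessions since change, 1-based
            else:
                miss += 1
                delays.append(horizon)  # censored at the horizon
        pfd[k] = false_det / n
        pnd[k] = miss / n
        add[k] = float(np.mean(delays)) if delays else np.nan

    eer, eer_tau = _eer_crossing(thresholds, pfd, pnd)
    add_at_eer = float(np.interp(eer_tau, thresholds, add))
    med = _median_detected_delay(trajs, eer_tau)
    return AFDMetrics(thresholds, pfd, pnd, add, eer, eer_tau, add_at_eer, med)


def _eer_crossing(tau: np.ndarray, pfd: np.ndarray, pnd: np.ndarray) -> tuple[float, float]:
    """PFD = PND crossing by linear interpolation along the threshold grid."""
    diff = pfd - pnd  # nonincreasing-ish: starts >= 0, ends <= 0
    sign = np.sign(diff)
    idx = np.flatnonzero(sign[:-1] * sign[1:] <= 0)
    if len(idx) == 0:
        k = int(np.argmin(np.abs(diff)))
        return float((pfd[k] + pnd[k]) / 2), float(tau[k])
    k = int(idx[0])
    d0, d1 = diff[k], diff[k + 1]
    w = 0.0 if d0 == d1 else d0 / (d0 - d1)
    eer_tau = tau[k] + w * (tau[k + 1] - tau[k])
    eer = pfd[k] + w * (pfd[k + 1] - pfd[k])
    eer2 = pnd[k] + w * (pnd[k + 1] - pnd[k])
    return float((eer + eer2) / 2), float(eer_tau)


def _median_detected_delay(trajs, tau: float) -> float:
    delays = []
    for S, change in trajs:
        post = S[change:]
        crossed = np.flatnonzero(post >= tau)
        if len(crossed):
            delays.append(crossed[0] + 1)
    return float(np.median(delays)) if delays else np.nan


def simulate_afd_sequences(
    folds,
    n_sequences_per_participant: int = 4,
    n_rest: int = 15,
    n_fatigue: int = 15,
    density_mode: str = "participant_remaining",
    rng: Union[int, np.random.Generator, None] = None,
    min_per_class: int = 5,
) -> list[tuple[np.ndarray, int]]:
    """Build rest-then-fatigue LLR sequences from LOO fold outputs.

    For each participant, scalar scores are the centroid-axis projections
    of their held-out fatigue-space embeddings (axis from that fold's
    training centroids).  Each simulated sequence concatenates ``n_rest``
    rest scores followed by ``n_fatigue`` fatigue scores drawn without
    replacement from the participant's pool (with replacement only if the
    pool is too small).

    ``density_mode`` picks where f_R/f_F come from:

    * ``participant_remaining`` — the participant's held-out scores *not*
      drawn into the sequence (the evaluation protocol used with
      precomputed cross-validated scores);
    * ``training_folds`` — the training participants' scores (fully
      subject-independent, usable in deployment).
    """
    from .sessions import FATIGUE as _F, REST as _R

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out: list[tuple[np.ndarray, int]] = []
    for fold in folds:
        cr = fold.train_rest_embeddings.mean(axis=0)
        cf = fold.train_fatigue_embeddings.mean(axis=0)
        proj = lambda E: project_to_scalar(
            E, method="centroid_axis", rest_centroid=cr, fatigue_centroid=cf
        )
        pr = proj(fold.heldout_embeddings[fold.heldout_labels == _R])
        pf = proj(fold.heldout_embeddings[fold.heldout_labels == _F])
        if density_mode == "training_folds":
            dens = estimate_densities(
                proj(fold.train_rest_embeddings), proj(fold.train_fatigue_embeddings)
            )
        for _ in range(n_sequences_per_participant):
            if density_mode == "participant_remaining":
                r_seq, r_rem = _split_draw(rng, pr, n_rest, min_per_class)
                f_seq, f_rem = _split_draw(rng, pf, n_fatigue, min_per_class)
                dens = estimate_densities(r_rem, f_rem, min_per_class=min_per_class)
            elif density_mode == "training_folds":
                r_seq = pr[rng.choice(len(pr), size=n_rest, replace=len(pr) < n_rest)]
                f_seq = pf[rng.choice(len(pf), size=n_fatigue, replace=len(pf) < n_fatigue)]
            else:
                raise ValueError(f"unknown density_mode {density_mode!r}")
            scores = np.concatenate([r_seq, f_seq])
            out.append((llr(scores, dens), n_rest))
    return out


def _split_draw(
    rng: np.random.Generator, pool: np.ndarray, k: int, min_remaining: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw k sequence scores and a disjoint remainder for density fitting.

    With a large pool the sequence is drawn without replacement and the
    remainder is everything else; with a small pool, ``min_remaining``
    scores are reserved for the densities first and the sequence is drawn
    with replacement from the rest.
    """
    n = len(pool)
    if n < min_remaining + 1:
        raise ValueError(
            f"participant pool of {n} scores cannot support sequence simulation "
            f"with {min_remaining} density scores reserved"
        )
    perm = rng.permutation(n)
    if n >= k + min_remaining:
        return pool[perm[:k]], pool[perm[k:]]
    seq_part = perm[: n - min_remaining]
    seq = pool[rng.choice(seq_part, size=k, replace=True)]
    return seq, pool[perm[n - min_remaining :]]


def afd_sequences_from_scores(
    rest_scores_by_seq: Sequence[np.ndarray],
    fatigue_scores_by_seq: Sequence[np.ndarray],
    densities: ScoreDensities,
) -> list[tuple[np.ndarray, int]]:
    """Concatenate rest-then-fatigue score sequences into LLR sequences.

    Mirrors the continuous-detection evaluation construction: each sequence
    starts rested and switches to fatigue at a known change point.
    """
    out = []
    for r, f in zip(rest_scores_by_seq, fatigue_scores_by_seq):
        scores = np.concatenate([r, f])
        out.append((llr(scores, densities), len(r)))
    return out


# ---------------------------------------------------------------------------
# real-world daily trend


def daily_fatigue_trend(
    sessions: Sequence[KeystrokeSession],
    scorer: Callable[[KeystrokeSession], float],
    max_gap_hours: float = 2.0,
    n_boot: int = 300,
    random_state: int = 0,
) -> pd.DataFrame:
    """Hourly aggregate of consecutive-session fatigue scores.

    For each participant, sessions are ordered by wall-clock start; each
    consecutive pair within the same day and less than ``max_gap_hours``
    apart contributes one score — the later session's scalar fatigue score
    relative to the participant's running reference (the mean score of all
    of their earlier sessions).  Scores are binned by the later session's
    hour of day; each bin gets the pooled mean and a bootstrap 95% CI.

    Returns a DataFrame (hour, mean, ci_low, ci_high, n); hours with no
    eligible pair are absent (missing, not zero).
    """
    rng = np.random.default_rng(random_state)
    by_pid: dict[str, list[KeystrokeSession]] = {}
    for s in sessions:
        if s.start_time is None:
            raise ValueError("daily trend needs wall-clock start times on every session")
        by_pid.setdefault(s.participant_id, []).append(s)

    binned: dict[int, list[float]] = {}
    for pid, ss in by_pid.items():
        ss = sorted(ss, key=lambda s: s.start_time)
        raw = np.array([scorer(s) for s in ss])
        running_mean = np.concatenate([[raw[0]], np.cumsum(raw)[:-1] / np.arange(1, len(raw))])
        for i in range(1, len(ss)):
            earlier, later = ss[i - 1], ss[i]
            if later.start_time.date() != earlier.start_time.date():
                continue
            gap_h = (later.start_time - earlier.start_time).total_seconds() / 3600.0
            if gap_h >= max_gap_hours:
                continue
            score = raw[i] - running_mean[i]
            binned.setdefault(later.start_time.hour, []).append(float(score))

    rows = []
    for hour in sorted(binned):
        vals = np.array(binned[hour])
        boots = np.array(
            [vals[rng.integers(len(vals), size=len(vals))].mean() for _ in range(n_boot)]
        )
        rows.append(
            {
                "hour": hour,
                "mean": float(vals.mean()),
                "ci_low": float(np.percentile(boots, 2.5)),
                "ci_high": float(np.percentile(boots, 97.5)),
                "n": int(len(vals)),
            }
        )
    return pd.DataFrame(rows, columns=["hour", "mean", "ci_low", "ci_high", "n"])


def make_axis_scorer(
    backbone,
    head,
    rest_centroid: np.ndarray,
    fatigue_centroid: np.ndarray,
) -> Callable[[KeystrokeSession], float]:
    """Session -> scalar fatigue score via embed, head, centroid-axis projection."""
    from .io import segment_session

    def scorer(session: KeystrokeSession) -> float:
        w = segment_session(session, policy="first_only")[0]
        g = head.transform(backbone.transform([w]))
        return float(
            project_to_scalar(
                g,
                method="centroid_axis",
                rest_centroid=rest_centroid,
                fatigue_centroid=fatigue_centroid,
            )[0]
        )

    return scorer
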