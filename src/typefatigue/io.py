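"""Reading, validating, featurizing and windowing keystroke event data.

Raw keystroke logs arrive as delimited text with one row per key event
(participant, session, press time, release time, optional keycode).  This
module parses such files into :class:`~typefatigue.sessions.KeystrokeSession`
objects, converts timestamps to seconds, extracts the four per-key timing
features, and cuts long sessions into fixed 150-key analysis windows.

Keycodes are dropped immediately after parsing for privacy: no downstream
computation ever reads them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .sessions import (
    FATIGUE,
    N_FEATURES,
    REST,
    UNKNOWN,
    WINDOW_KEYS,
    FeatureMatrix,
    KeystrokeEvent,
    KeystrokeSession,
)

logger = logging.getLogger(__name__)

#: seconds per unit, by resolution token
_RESOLUTION_FACTORS = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6}


class SchemaError(ValueError):
    """A required column is missing or the schema config is invalid."""


class ValidationError(ValueError):
    """A row violates a timing invariant (e.g. release before press)."""


@dataclass
class SessionSchema:
    """Column mapping and unit declaration for delimited keystroke logs."""

    participant: str = "participant"
    session: str = "session"
    press_time: str = "press_time"
    release_time: str = "release_time"
    keycode: Optional[str] = None
    label: Optional[str] = None
    wall_clock: Optional[str] = None
    resolution: str = "s"
    delimiter: str = ","

    @classmethod
    def from_dict(cls, d: dict) -> "SessionSchema":
        return cls(**d)


def read_sessions(source, schema: Optional[SessionSchema] = None) -> list[KeystrokeSession]:
    """Parse delimited event records into per-(participant, session) sessions.

    Parameters
    ----------
    source : path or file-like
        Delimited text with a header row.
    schema : SessionSchema
        Column mapping; ``resolution`` declares the input time unit.

    Rows with unparseable times are dropped and counted (logged); a row
    whose release precedes its press raises :class:`ValidationError` naming
    the offending row.
    """
    schema = schema or SessionSchema()
    df = pd.read_csv(source, sep=schema.delimiter)
    required = [schema.participant, schema.session, schema.press_time, schema.release_time]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}; found {list(df.columns)}")

    press = pd.to_numeric(df[schema.press_time], errors="coerce")
    release = pd.to_numeric(df[schema.release_time], errors="coerce")
    bad = press.isna() | release.isna()
    n_malformed = int(bad.sum())
    if n_malformed:
        logger.warning("dropping %d malformed row(s) with unparseable times", n_malformed)
        df = df.loc[~bad].copy()
        press, release = press[~bad], release[~bad]

    inverted = release < press
    if inverted.any():
        row = int(np.flatnonzero(inverted.to_numpy())[0])
        raise ValidationError(
            f"release_time < press_time at input row {df.index[inverted][0]} "
            f"(first of {int(inverted.sum())} such rows)"
        )

    factor = _resolution_factor(schema.resolution)
    df = df.assign(_press=press * factor, _release=release * factor)

    sessions: list[KeystrokeSession] = []
    for (pid, _sid), grp in df.groupby([schema.participant, schema.session], sort=True):
        grp = grp.sort_values("_press", kind="stable")
        events = [
            KeystrokeEvent(p, r, int(k) if k is not None and not pd.isna(k) else None)
            for p, r, k in zip(
                grp["_press"],
                grp["_release"],
                grp[schema.keycode] if schema.keycode else [None] * len(grp),
            )
        ]
        label = UNKNOWN
        if schema.label and schema.label in grp.columns:
            label = str(grp[schema.label].iloc[0])
        start = None
        if schema.wall_clock and schema.wall_clock in grp.columns:
            start = pd.to_datetime(grp[schema.wall_clock].iloc[0]).to_pydatetime()
        sessions.append(
            KeystrokeSession(
                participant_id=str(pid), events=events, label=label, start_time=start
            )
        )
    return sessions


def _resolution_factor(token: str) -> float:
    try:
        return _RESOLUTION_FACTORS[token]
    except KeyError:
        raise SchemaError(
            f"unknown time resolution {token!r}; expected one of {sorted(set(_RESOLUTION_FACTORS))}"
        ) from None


def normalize_timestamps(session: KeystrokeSession, input_resolution: str) -> KeystrokeSession:
    """Convert all event times to seconds from the declared input unit."""
    factor = _resolution_factor(input_resolution)
    if factor == 1.0:
        return session
    events = [
        KeystrokeEvent(e.press_time * factor, e.release_time * factor, e.keycode)
        for e in session.events
    ]
    return session.with_events(events)


def extract_features(session: KeystrokeSession) -> np.ndarray:
    """Per-key timing features, shape (L, 4), seconds.

    Row ``i`` holds (hold_i, flight_i, IKL_i, IRL_i) with
    flight = press_i - press_{i-1}, IKL = press_i - release_{i-1},
    IRL = release_i - release_{i-1}.  Row 0 has no predecessor, so its
    flight/IKL/IRL are zero.  Negative IKL (key rollover) is preserved.
    """
    press = np.array([e.press_time for e in session.events])
    release = np.array([e.release_time for e in session.events])
    n = len(press)
    out = np.zeros((n, N_FEATURES))
    out[:, 0] = release - press
    if n > 1:
        out[1:, 1] = press[1:] - press[:-1]
        out[1:, 2] = press[1:] - release[:-1]
        out[1:, 3] = release[1:] - release[:-1]
    return out


def fix_length(matrix: np.ndarray, target_length: int = WINDOW_KEYS, **meta) -> FeatureMatrix:
    """Zero-pad or head-truncate an (L, 4) matrix to the fixed window size."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[1] != N_FEATURES:
        raise ValueError(f"expected (L, {N_FEATURES}) matrix, got {matrix.shape}")
    L = matrix.shape[0]
    if L == 0:
        raise ValueError("cannot fix length of an empty matrix")
    out = np.zeros((target_length, N_FEATURES))
    valid = min(L, target_length)
    out[:valid] = matrix[:valid]
    return FeatureMatrix(out, valid_length=valid, **meta)


def segment_session(
    session: KeystrokeSession,
    window_keys: int = WINDOW_KEYS,
    policy: str = "nonoverlapping",
    min_window_keys: int = 30,
) -> list[FeatureMatrix]:
    """Cut a featurized session into fixed-size key windows.

    ``nonoverlapping`` emits consecutive ``window_keys``-key windows; a
    final partial window is kept (zero-padded) only if it has at least
    ``min_window_keys`` keys.  ``first_only`` emits a single window from
    the session head.
    """
    feats = extract_features(session)
    meta = dict(
        participant_id=session.participant_id,
        label=session.label,
        start_time=session.start_time,
    )
    if policy == "first_only":
        return [fix_length(feats[:window_keys], window_keys, **meta)]
    if policy != "nonoverlapping":
        raise ValueError(f"unknown segmentation policy {policy!r}")
    windows = []
    for start in range(0, feats.shape[0], window_keys):
        chunk = feats[start : start + window_keys]
        if chunk.shape[0] < window_keys and chunk.shape[0] < min_window_keys:
            continue
        windows.append(fix_length(chunk, window_keys, **meta))
    return windows


def segment_session_by_time(session: KeystrokeSession, window_seconds: float = 300.0) -> list[np.ndarray]:
    """Variable-length feature matrices for consecutive time windows.

    Used by the statistical baselines' long-window setup, where a sample is
    all keys typed within a fixed time span rather than a fixed key count.
    """
    feats = extract_features(session)
    press = np.array([e.press_time for e in session.events])
    t0 = press[0]
    out = []
    idx = np.floor((press - t0) / window_seconds).astype(int)
    for w in range(idx.max() + 1):
        chunk = feats[idx == w]
        if chunk.shape[0] >= 2:
            out.append(chunk)
    return out


def split_stream(
    session: KeystrokeSession, pause_threshold_s: float = 60.0
) -> list[KeystrokeSession]:
    """Split a continuous event stream at typing pauses.

    A new session starts whenever the gap between consecutive press times
    exceeds ``pause_threshold_s``.  Each output session carries a wall-clock
    start derived from the stream's ``start_time`` plus the offset of its
    first press.
    """
    press = np.array([e.press_time for e in session.events])
    breaks = np.flatnonzero(np.diff(press) > pause_threshold_s) + 1
    pieces = np.split(np.arange(len(press)), breaks)
    out = []
    base = session.start_time
    t0 = press[0]
    for piece in pieces:
        ev = [session.events[i] for i in piece]
        start = None
        if base is not None:
            start = base + timedelta(seconds=float(ev[0].press_time - t0))
        out.append(
            KeystrokeSession(
                participant_id=session.participant_id,
                events=ev,
                label=session.label,
                start_time=start,
                context_tag=session.context_tag,
            )
        )
    return out


def featurize_sessions(
    sessions: Iterable[KeystrokeSession], policy: str = "nonoverlapping", min_window_keys: int = 30
) -> list[FeatureMatrix]:
    """Windows for every session, flattened in input order."""
    out: list[FeatureMatrix] = []
    for s in sessions:
        out.extend(segment_session(s, policy=policy, min_window_keys=min_window_keys))
    return out


def write_sessions(sessions: Iterable[KeystrokeSession], path, schema: Optional[SessionSchema] = None) -> None:
    """Write sessions to delimited text in the `read_sessions` schema."""
    schema = schema or SessionSchema()
    rows = []
    for i, s in enumerate(sessions):
        for e in s.events:
            row = {
                schema.participant: s.participant_id,
                schema.session: i,
                schema.press_time: e.press_time,
                schema.release_time: e.release_time,
            }
            if schema.label:
                row[schema.label] = s.label
            if schema.wall_clock:
                row[schema.wall_clock] = s.start_time.isoformat() if s.start_time else ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, sep=schema.delimiter)
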