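"""Core containers for keystroke timing data.

A *keystroke session* is one sitting at the keyboard: an ordered stream of
press/release event pairs for a single participant, optionally labelled with
the participant's state (``rest`` / ``fatigue``) and stamped with a
wall-clock start time.  All downstream analysis consumes sessions through
the fixed-size timing representation :class:`FeatureMatrix`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Optional, Sequence

import numpy as np

#: Canonical state labels.
REST = "rest"
FATIGUE = "fatigue"
UNKNOWN = "unknown"
LABELS = (REST, FATIGUE, UNKNOWN)

#: Number of keystrokes per model input window.
WINDOW_KEYS = 150
#: Timing features per keystroke (hold, flight, inter-key, inter-release).
N_FEATURES = 4


@dataclass(frozen=True)
class KeystrokeEvent:
    """One key press/release pair, times in seconds."""

    press_time: float
    release_time: float
    keycode: Optional[int] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.press_time) and math.isfinite(self.release_time)):
            raise ValueError("keystroke event times must be finite")
        if self.release_time < self.press_time:
            raise ValueError(
                f"release_time ({self.release_time}) earlier than "
                f"press_time ({self.press_time})"
            )

    @property
    def hold(self) -> float:
        return self.release_time - self.press_time


@dataclass
class KeystrokeSession:
    """Ordered keystroke events for one participant sitting."""

    participant_id: str
    events: list[KeystrokeEvent]
    label: str = UNKNOWN
    start_time: Optional[datetime] = None
    context_tag: str = ""

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("session must contain at least one event")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        presses = [e.press_time for e in self.events]
        if any(b < a for a, b in zip(presses, presses[1:])):
            raise ValueError("events must be ordered by non-decreasing press time")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def duration(self) -> float:
        """Elapsed seconds from first press to last release."""
        return self.events[-1].release_time - self.events[0].press_time

    def with_events(self, events: Sequence[KeystrokeEvent]) -> "KeystrokeSession":
        return replace(self, events=list(events))


@dataclass
class FeatureMatrix:
    """Fixed-size 150x4 timing representation of (up to) 150 keystrokes.

    Columns, in seconds: hold, flight (press->press), inter-key latency
    (release->press; negative under rollover), inter-release latency.
    Rows at index >= ``valid_length`` are zero padding.
    """

    values: np.ndarray
    valid_length: int
    participant_id: str = ""
    label: str = UNKNOWN
    start_time: Optional[datetime] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (WINDOW_KEYS, N_FEATURES):
            raise ValueError(
                f"expected shape {(WINDOW_KEYS, N_FEATURES)}, got {self.values.shape}"
            )
        if not 1 <= self.valid_length <= WINDOW_KEYS:
            raise ValueError(f"valid_length must be in 1..{WINDOW_KEYS}")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        if np.any(self.values[self.valid_length:] != 0.0):
            raise ValueError("rows beyond valid_length must be zero")

    def trimmed(self) -> np.ndarray:
        """The non-padded part, shape (valid_length, 4)."""
        return self.values[: self.valid_length]


def stack_features(mats: Sequence[FeatureMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature matrices into (n, 150, 4) values and (n,) valid lengths."""
    x = np.stack([m.values for m in mats])
    lengths = np.array([m.valid_length for m in mats], dtype=np.int64)
    return x, lengths
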