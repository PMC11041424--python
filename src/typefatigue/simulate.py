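"""Synthetic typist simulator.

Generates keystroke corpora with the statistical structure of the three
acquisition protocols the detection pipeline targets:

* a *pretraining* corpus — many typists, short (~70-key) free-text sessions,
  no fatigue labels, identity signal carried by between-typist differences
  in timing distributions;
* a *supervised* cohort — a small cohort with long (15-minute) sessions
  captured in labelled rest and fatigue states;
* a *daily stream* — short (~3-minute) unlabelled sessions stamped with
  wall-clock times, whose latent fatigue follows a circadian curve.

Timing model
------------
Hold times and inter-key latencies are i.i.d. log-normal per typist:
latencies are positive and right-skewed, and log-normal parameters around
0.1 s (hold) and 0.2 s (inter-key) keep every feature well below 1 second.
Fatigue acts multiplicatively: at latent level ``z`` in [0, 1] the log-mean
shifts by ``z * log(mean_scale)`` and the log-sd is inflated by
``1 + z * (sd_scale - 1)`` — slowed *and* more erratic typing.  Key
rollover (pressing the next key before releasing the previous one) occurs
with a per-typist probability and yields negative inter-key latencies.

Every generator is driven by an explicit seed and is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from typing import Optional, Sequence, Union

import numpy as np

from .sessions import FATIGUE, REST, UNKNOWN, KeystrokeEvent, KeystrokeSession

#: Default multiplicative fatigue effect (slowing, dispersion inflation).
DEFAULT_MEAN_SCALE = 1.3
DEFAULT_SD_SCALE = 1.5


@dataclass
class TypistProfile:
    """Latent timing parameters of one synthetic typist."""

    user_id: str
    hold_lognorm: tuple[float, float] = (math.log(0.11), 0.25)
    ikl_lognorm: tuple[float, float] = (math.log(0.22), 0.35)
    rollover_prob: float = 0.10
    fatigue_effect: tuple[float, float] = (DEFAULT_MEAN_SCALE, DEFAULT_SD_SCALE)
    circadian: tuple[float, float, float] = (0.8, 23.0, 0.15)  # amplitude, acrophase h, post-lunch dip
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.hold_lognorm[1] < 0 or self.ikl_lognorm[1] < 0:
            raise ValueError("log-sd must be nonnegative")
        if self.fatigue_effect[0] < 1 or self.fatigue_effect[1] < 1:
            raise ValueError("fatigue scales must be >= 1 (fatigue slows typing)")
        if not 0 <= self.circadian[0] <= 1:
            raise ValueError("circadian amplitude must be in [0, 1]")


@dataclass
class SimulatedCorpus:
    """Sessions plus per-session latent fatigue ground truth."""

    sessions: list[KeystrokeSession]
    ground_truth: np.ndarray
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ground_truth = np.asarray(self.ground_truth, dtype=np.float64)
        if len(self.sessions) != len(self.ground_truth):
            raise ValueError("ground_truth must align 1:1 with sessions")


@dataclass
class PopulationConfig:
    """Hyper-distributions from which per-typist profiles are drawn.

    ``between_user_sd`` scales the spread of per-typist log-means (0 makes
    all typists statistically identical — a negative control for identity
    pretraining).  Per-typist fatigue effects are drawn around the nominal
    scales with a uniform +-60% spread on the excess over 1, so cohorts
    genuinely mix strong and weak responders.
    """

    hold_log_mean: float = math.log(0.11)
    hold_log_sd: float = 0.25
    ikl_log_mean: float = math.log(0.22)
    ikl_log_sd: float = 0.35
    between_user_sd: float = 1.0
    mean_scale: float = DEFAULT_MEAN_SCALE
    sd_scale: float = DEFAULT_SD_SCALE
    rollover_mean: float = 0.10
    effect_spread: float = 0.6


def draw_profile(rng: np.random.Generator, user_id: str, pop: PopulationConfig) -> TypistProfile:
    """Draw one typist from the population hyper-distributions."""
    b = pop.between_user_sd
    hold_mu = pop.hold_log_mean + 0.18 * b * rng.standard_normal()
    ikl_mu = pop.ikl_log_mean + 0.25 * b * rng.standard_normal()
    hold_sigma = pop.hold_log_sd * float(np.exp(0.2 * b * rng.standard_normal()))
    ikl_sigma = pop.ikl_log_sd * float(np.exp(0.2 * b * rng.standard_normal()))
    rollover = float(np.clip(rng.normal(pop.rollover_mean, 0.04 * b), 0.0, 0.5))
    u = rng.uniform(1 - pop.effect_spread, 1 + pop.effect_spread)
    mean_scale = 1.0 + (pop.mean_scale - 1.0) * u
    sd_scale = 1.0 + (pop.sd_scale - 1.0) * u
    return TypistProfile(
        user_id=user_id,
        hold_lognorm=(hold_mu, hold_sigma),
        ikl_lognorm=(ikl_mu, ikl_sigma),
        rollover_prob=rollover,
        fatigue_effect=(mean_scale, sd_scale),
        rng_seed=int(rng.integers(2**31 - 1)),
    )


def _level(state: Union[str, float]) -> float:
    if isinstance(state, str):
        try:
            return {REST: 0.0, FATIGUE: 1.0}[state]
        except KeyError:
            raise ValueError(f"invalid state token {state!r}") from None
    z = float(state)
    if not 0.0 <= z <= 1.0:
        raise ValueError("latent fatigue level must lie in [0, 1]")
    return z


def sample_session(
    profile: TypistProfile,
    state: Union[str, float],
    n_keys: Optional[int] = None,
    duration_s: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    start_time: Optional[datetime] = None,
    label: Optional[str] = None,
) -> KeystrokeSession:
    """Sample one keystroke session at the given fatigue state/level.

    Exactly one of ``n_keys`` or ``duration_s`` must be given; with
    ``duration_s`` keys accumulate until the elapsed time is reached.
    """
    if (n_keys is None) == (duration_s is None):
        raise ValueError("specify exactly one of n_keys or duration_s")
    rng = rng if rng is not None else np.random.default_rng(profile.rng_seed)
    z = _level(state)
    mean_scale, sd_scale = profile.fatigue_effect
    shift = z * math.log(mean_scale)
    inflate = 1.0 + z * (sd_scale - 1.0)
    hold_mu, hold_sd = profile.hold_lognorm[0] + shift, profile.hold_lognorm[1] * inflate
    ikl_mu, ikl_sd = profile.ikl_lognorm[0] + shift, profile.ikl_lognorm[1] * inflate

    events: list[KeystrokeEvent] = []
    press = 0.0
    hold = float(rng.lognormal(hold_mu, hold_sd))
    events.append(KeystrokeEvent(press, press + hold))
    i = 1
    while True:
        if n_keys is not None and i >= n_keys:
            break
        if duration_s is not None and events[-1].release_time >= duration_s:
            break
        prev_hold = events[-1].hold
        if rng.uniform() < profile.rollover_prob:
            ikl = -rng.uniform(0.1, 0.8) * prev_hold  # next press lands inside previous hold
        else:
            ikl = float(rng.lognormal(ikl_mu, ikl_sd))
        press = events[-1].release_time + ikl
        hold = float(rng.lognormal(hold_mu, hold_sd))
        events.append(KeystrokeEvent(press, press + hold))
        i += 1

    if label is None:
        label = REST if z == 0.0 else FATIGUE if z == 1.0 else UNKNOWN
    return KeystrokeSession(
        participant_id=profile.user_id, events=events, label=label, start_time=start_time
    )


def simulate_supervised_cohort(
    n_participants: int = 14,
    sessions_per_state: int = 2,
    session_minutes: float = 15.0,
    population: Optional[PopulationConfig] = None,
    seed: int = 0,
) -> SimulatedCorpus:
    """Labelled rest/fatigue cohort (long supervised sessions).

    Defaults mirror the supervised acquisition protocol the pipeline is
    trained on: 14 participants, 2 rest + 2 fatigue sessions each,
    15 minutes per session.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    pop = population or PopulationConfig()
    rng = np.random.default_rng(seed)
    sessions, truth = [], []
    for i in range(n_participants):
        profile = draw_profile(rng, f"P{i:03d}", pop)
        for state in (REST, FATIGUE):
            for _ in range(sessions_per_state):
                sessions.append(
                    sample_session(
                        profile, state, duration_s=session_minutes * 60.0, rng=rng
                    )
                )
                truth.append(_level(state))
    manifest = {
        "kind": "supervised",
        "n_participants": n_participants,
        "sessions_per_state": sessions_per_state,
        "session_minutes": session_minutes,
        "population": asdict(pop),
        "seed": seed,
    }
    return SimulatedCorpus(sessions, np.array(truth), manifest)


def circadian_level(
    hour: float,
    amplitude: float = 0.8,
    acrophase_hour: float = 23.0,
    postlunch_dip: float = 0.15,
) -> float:
    """Deterministic latent fatigue level at an hour of day, in [0, 1].

    A cosine peaking at ``acrophase_hour`` (late-evening sleep pressure)
    plus a Gaussian bump around 14:00 emulating the post-lunch dip.
    """
    base = amplitude * (0.5 + 0.5 * math.cos(2 * math.pi * (hour - acrophase_hour) / 24.0))
    dip = postlunch_dip * math.exp(-0.5 * ((hour - 14.0) / 1.5) ** 2)
    return float(np.clip(base + dip, 0.0, 1.0))


def simulate_daily_stream(
    profile_or_n: Union[TypistProfile, int] = 4,
    n_days: int = 7,
    sessions_per_day: int = 24,
    session_minutes: float = 3.0,
    noise_sd: float = 0.05,
    population: Optional[PopulationConfig] = None,
    start: Optional[datetime] = None,
    seed: int = 0,
) -> SimulatedCorpus:
    """Unlabelled timestamped session stream with circadian latent fatigue.

    Sessions are scheduled evenly over each day (default hourly) with a few
    minutes of jitter; each session's latent fatigue is the typist's
    circadian curve at that hour plus Gaussian noise, clipped to [0, 1],
    and is recorded in ``ground_truth``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(profile_or_n, TypistProfile):
        profiles = [profile_or_n]
    else:
        pop = population or PopulationConfig()
        profiles = [draw_profile(rng, f"S{i:03d}", pop) for i in range(profile_or_n)]
    start = start or datetime(2022, 3, 7, 0, 0)
    sessions, truth = [], []
    for profile in profiles:
        amp, acro, dip = profile.circadian
        for day in range(n_days):
            for k in range(sessions_per_day):
                hour = 24.0 * k / sessions_per_day + rng.uniform(0, 5.0 / 60.0)
                z = circadian_level(hour, amp, acro, dip) + rng.normal(0, noise_sd)
                z = float(np.clip(z, 0.0, 1.0))
                when = start + timedelta(days=day, hours=hour)
                sessions.append(
                    sample_session(
                        profile,
                        z,
                        duration_s=session_minutes * 60.0,
                        rng=rng,
                        start_time=when,
                        label=UNKNOWN,
                    )
                )
                truth.append(z)
    manifest = {
        "kind": "daily_stream",
        "n_participants": len(profiles),
        "n_days": n_days,
        "sessions_per_day": sessions_per_day,
        "session_minutes": session_minutes,
        "seed": seed,
    }
    return SimulatedCorpus(sessions, np.array(truth), manifest)


def simulate_pretraining_corpus(
    n_users: int = 200,
    sessions_per_user: int = 15,
    keys_per_session: int = 70,
    population: Optional[PopulationConfig] = None,
    seed: int = 0,
) -> SimulatedCorpus:
    """Many-typist short-session corpus for identity pretraining.

    Fatigue-unlabelled; the learnable signal is between-typist separation
    of the log-normal timing parameters.  Setting
    ``population.between_user_sd = 0`` makes typists indistinguishable (a
    negative control under which identity pretraining must fail).
    """
    if n_users < 2:
        raise ValueError("need at least 2 users")
    pop = population or PopulationConfig()
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(n_users):
        profile = draw_profile(rng, f"U{i:05d}", pop)
        for _ in range(sessions_per_user):
            sessions.append(
                sample_session(profile, REST, n_keys=keys_per_session, rng=rng, label=UNKNOWN)
            )
    manifest = {
        "kind": "pretraining",
        "n_users": n_users,
        "sessions_per_user": sessions_per_user,
        "keys_per_session": keys_per_session,
        "population": asdict(pop),
        "seed": seed,
    }
    return SimulatedCorpus(sessions, np.zeros(len(sessions)), manifest)
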