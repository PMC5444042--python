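"""Synthetic wearable biometric data generator.

Produces raw-format data mimicking what a wrist-worn fitness tracker records:

* heart rate as irregularly timed BPM events (a few seconds to a few minutes
  apart), and
* activity episodes reported only as interval totals (total calories and
  total footsteps per episode).

The generator is built so that, after preprocessing to a per-minute grid, the
series reproduce the statistical signatures typical of tracker data:

* calories and footsteps strongly positively correlated (both are produced by
  the same activity bouts),
* heart rate essentially uncorrelated with either channel (coupling is off by
  default),
* step/calorie autocorrelation confined to the episode-duration scale, and
* a tunable degree of day-to-day schedule regularity per user.

All randomness flows from ``UserProfile.seed`` through named
``numpy.random.SeedSequence`` child streams (episodes, heart-rate process,
heart-rate sampling), so identical profiles give bitwise-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440

__all__ = [
    "UserProfile",
    "RawHeartRateLog",
    "ActivityEpisode",
    "simulate_episodes",
    "simulate_heart_rate",
    "simulate_user",
    "heart_rate_minute_process",
    "steps_per_minute",
]


@dataclass(frozen=True)
class UserProfile:
    """Parameters describing one simulated tracker wearer.

    Attributes
    ----------
    seed:
        Master seed; every random stream derives from it.
    regularity:
        In [0, 1]. Mixture weight between a fixed daily template of episode
        start times (1 = the same clock times every day) and uniformly random
        start times (0, the default). Any nonzero value plants genuine
        autocorrelation at the template's separation lags — a repeating daily
        schedule is long-range structure — so the default keeps the step
        series free of structure beyond the episode scale; regularity is
        raised explicitly when the regular-vs-irregular user contrast is the
        object of study.
    episode_rate:
        Expected activity episodes per day. Rounded to the nearest integer to
        give the number of daily episode slots.
    episode_duration_mean, episode_duration_sd:
        Episode duration distribution (minutes, truncated normal).
    steps_per_min_mean, steps_per_min_sd:
        Walking cadence during an episode (steps/minute, truncated normal,
        drawn once per episode).
    kcal_per_step:
        Activity energy cost per footstep.
    kcal_noise_frac:
        Relative SD of per-episode calorie noise (the tracker's energy
        equation depends on more than footsteps, so calorie totals are not
        an exact function of steps).
    kcal_base_per_min:
        Resting energy expenditure, exported as zero-step background episodes.
    hr_baseline, hr_circadian_amp:
        Mean BPM and the amplitude of a 24-h sinusoid peaking at 17:00.
    hr_ar_coef, hr_noise_sd:
        AR(1) persistence coefficient (in [0, 1)) and innovation SD of the
        minute-scale heart-rate fluctuation process.
    hr_activity_coupling:
        BPM added per concurrent step/minute. 0 by default, which makes heart
        rate statistically independent of the activity channels.
    hr_sampling_interval_mean:
        Mean of the exponential inter-event interval of the heart-rate
        logger, in seconds.
    duration_days:
        Length of the simulated recording.
    start_time:
        Timestamp of minute 0 (midnight-aligned, timezone-naive).
    """

    seed: int = 0
    regularity: float = 0.0
    episode_rate: float = 8.0
    episode_duration_mean: float = 15.0
    episode_duration_sd: float = 5.0
    steps_per_min_mean: float = 80.0
    steps_per_min_sd: float = 15.0
    kcal_per_step: float = 0.04
    kcal_noise_frac: float = 0.25
    kcal_base_per_min: float = 1.2
    hr_baseline: float = 72.0
    hr_circadian_amp: float = 6.0
    hr_ar_coef: float = 0.97
    hr_noise_sd: float = 1.5
    hr_activity_coupling: float = 0.0
    hr_sampling_interval_mean: float = 120.0
    duration_days: int = 30
    start_time: str = "2016-01-04 00:00:00"

    def __post_init__(self) -> None:
        if not 0.0 <= self.regularity <= 1.0:
            raise ValueError("regularity must lie in [0, 1]")
        if self.episode_rate <= 0:
            raise ValueError("episode_rate must be positive")
        if self.episode_duration_mean <= 0:
            raise ValueError("episode_duration_mean must be positive")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if not 0.0 <= self.hr_ar_coef < 1.0:
            raise ValueError("hr_ar_coef must lie in [0, 1) for stationarity")
        if self.hr_sampling_interval_mean <= 0:
            raise ValueError("hr_sampling_interval_mean must be positive")
        slots = max(1, int(round(self.episode_rate)))
        if MINUTES_PER_DAY / slots <= self._duration_cap() + 1:
            raise ValueError(
                "episode_rate too high for the episode duration distribution"
            )

    def _duration_cap(self) -> float:
        # durations are truncated here so template slots can never collide
        return self.episode_duration_mean + 4.0 * self.episode_duration_sd

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_time)

    @property
    def n_minutes(self) -> int:
        return self.duration_days * MINUTES_PER_DAY

    def replace(self, **kwargs) -> "UserProfile":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ActivityEpisode:
    """A contiguous interval over which the tracker reports only totals."""

    start: pd.Timestamp
    end: pd.Timestamp
    total_calories: float
    total_steps: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("episode end must be after start")
        if self.total_calories < 0 or self.total_steps < 0:
            raise ValueError("episode totals must be nonnegative")

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start) / pd.Timedelta(minutes=1)


@dataclass
class RawHeartRateLog:
    """Irregularly sampled heart-rate events (strictly increasing times)."""

    times: pd.DatetimeIndex
    bpm: np.ndarray

    def __post_init__(self) -> None:
        self.bpm = np.asarray(self.bpm, dtype=float)
        if len(self.times) != len(self.bpm):
            raise ValueError("times and bpm must have equal length")
        if len(self.times) and not self.times.is_monotonic_increasing:
            raise ValueError("heart-rate timestamps must be increasing")
        if len(self.times) > 1 and (np.diff(self.times.asi8) <= 0).any():
            raise ValueError("heart-rate timestamps must be strictly increasing")
        if len(self.bpm) and (self.bpm <= 0).any():
            raise ValueError("bpm values must be positive")

    def __len__(self) -> int:
        return len(self.bpm)


def _streams(profile: UserProfile) -> dict[str, np.random.Generator]:
    """Named child RNG streams derived from the profile seed."""
    ss = np.random.SeedSequence(profile.seed)
    names = ("episodes", "hr_process", "hr_sampling")
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _daily_template(profile: UserProfile, rng: np.random.Generator) -> np.ndarray:
    """Template start minutes, one per equal slot of the day.

    Starts are drawn once per user and leave room for the truncation cap of
    the duration distribution, so template episodes can never overlap each
    other nor cross midnight.
    """
    slots = max(1, int(round(profile.episode_rate)))
    slot_len = MINUTES_PER_DAY / slots
    cap = profile._duration_cap()
    offsets = rng.uniform(0.0, slot_len - cap - 1.0, size=slots)
    return np.floor(np.arange(slots) * slot_len + offsets)


def _draw_duration(profile: UserProfile, rng: np.random.Generator) -> int:
    d = profile.episode_duration_mean
    if profile.episode_duration_sd > 0:
        d = rng.normal(profile.episode_duration_mean, profile.episode_duration_sd)
    d = float(np.clip(d, 1.0, profile._duration_cap()))
    return max(1, int(round(d)))


def simulate_episodes(
    profile: UserProfile, rng: np.random.Generator | None = None
) -> list[ActivityEpisode]:
    """Simulate non-overlapping activity episodes plus resting background.

    Each day realizes ``round(episode_rate)`` episodes. Per episode, the
    start time is the user's fixed daily template slot with probability
    ``regularity`` and uniform random otherwise; the duration and cadence are
    redrawn every day. Totals follow the tracker's bookkeeping::

        total_steps    = duration * cadence            (rounded)
        total_calories = kcal_base_per_min * duration + kcal_per_step * steps

    Minutes not covered by any activity episode are exported as zero-step
    background episodes of at most 60 minutes carrying only the resting burn,
    which keeps the episode CSV format uniform while leaving the step channel
    strictly activity-driven.
    """
    if rng is None:
        rng = _streams(profile)["episodes"]
    template = _daily_template(profile, rng)
    episodes: list[tuple[int, int]] = []  # (start_minute, end_minute) absolute
    for day in range(profile.duration_days):
        day0 = day * MINUTES_PER_DAY
        taken: list[tuple[int, int]] = []
        for slot, tmpl_start in enumerate(template):
            duration = _draw_duration(profile, rng)
            use_template = (
                profile.regularity >= 1.0 or rng.random() < profile.regularity
            )
            if use_template:
                start = int(tmpl_start)
                placed = True
            else:
                placed = False
                for _attempt in range(20):
                    start = int(rng.integers(0, MINUTES_PER_DAY - duration))
                    if all(
                        start + duration <= s or start >= e for s, e in taken
                    ):
                        placed = True
                        break
            if not placed:
                continue
            if any(start < e and start + duration > s for s, e in taken):
                # random draw collided with an occupied span on every attempt
                continue
            taken.append((start, start + duration))
        taken.sort()
        episodes.extend((day0 + s, day0 + e) for s, e in taken)

    out: list[ActivityEpisode] = []
    for s, e in episodes:
        duration = e - s
        cadence = profile.steps_per_min_mean
        if profile.steps_per_min_sd > 0:
            cadence = max(
                0.0, rng.normal(profile.steps_per_min_mean, profile.steps_per_min_sd)
            )
        steps = int(round(duration * cadence))
        activity_kcal = profile.kcal_per_step * steps
        if profile.kcal_noise_frac > 0:
            # the tracker's energy equation uses more than footsteps, so the
            # calorie total carries noise of its own
            activity_kcal *= max(0.0, rng.normal(1.0, profile.kcal_noise_frac))
        kcal = profile.kcal_base_per_min * duration + activity_kcal
        out.append(
            ActivityEpisode(
                start=profile.start + pd.Timedelta(minutes=s),
                end=profile.start + pd.Timedelta(minutes=e),
                total_calories=float(kcal),
                total_steps=steps,
            )
        )

    out.extend(_rest_episodes(profile, episodes))
    out.sort(key=lambda ep: ep.start)
    return out


def _rest_episodes(
    profile: UserProfile, activity: list[tuple[int, int]]
) -> list[ActivityEpisode]:
    """Fill every gap with <=60-min zero-step episodes of resting burn."""
    rest: list[ActivityEpisode] = []
    bounds = sorted(activity)
    cursor = 0
    gaps: list[tuple[int, int]] = []
    for s, e in bounds:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < profile.n_minutes:
        gaps.append((cursor, profile.n_minutes))
    for g0, g1 in gaps:
        for s in range(g0, g1, 60):
            e = min(s + 60, g1)
            rest.append(
                ActivityEpisode(
                    start=profile.start + pd.Timedelta(minutes=s),
                    end=profile.start + pd.Timedelta(minutes=e),
                    total_calories=profile.kcal_base_per_min * (e - s),
                    total_steps=0,
                )
            )
    return rest


def steps_per_minute(
    profile: UserProfile, episodes: list[ActivityEpisode]
) -> np.ndarray:
    """Per-minute step rate implied by the episode totals (activity only)."""
    steps = np.zeros(profile.n_minutes)
    for ep in episodes:
        if ep.total_steps == 0:
            continue
        s = int((ep.start - profile.start) / pd.Timedelta(minutes=1))
        e = int((ep.end - profile.start) / pd.Timedelta(minutes=1))
        steps[s:e] = ep.total_steps / (e - s)
    return steps


def heart_rate_minute_process(
    profile: UserProfile,
    episodes: list[ActivityEpisode] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Latent minute-resolution heart-rate process.

    baseline + circadian sinusoid (24-h period, peak at 17:00) + stationary
    AR(1) fluctuation + optional coupling to the concurrent step rate.
    """
    if rng is None:
        rng = _streams(profile)["hr_process"]
    n = profile.n_minutes
    minute_of_day = np.arange(n) % MINUTES_PER_DAY
    circadian = profile.hr_circadian_amp * np.sin(
        2.0 * np.pi * (minute_of_day / MINUTES_PER_DAY - 11.0 / 24.0)
    )
    phi, sd = profile.hr_ar_coef, profile.hr_noise_sd
    ar = np.zeros(n)
    if sd > 0:
        innov = rng.normal(0.0, sd, size=n)
        ar[0] = innov[0] / np.sqrt(1.0 - phi**2) if phi > 0 else innov[0]
        for t in range(1, n):
            ar[t] = phi * ar[t - 1] + innov[t]
    hr = profile.hr_baseline + circadian + ar
    if profile.hr_activity_coupling != 0.0 and episodes is not None:
        hr = hr + profile.hr_activity_coupling * steps_per_minute(profile, episodes)
    return np.maximum(hr, 1.0)


def simulate_heart_rate(
    profile: UserProfile,
    episodes: list[ActivityEpisode] | None = None,
    process_rng: np.random.Generator | None = None,
    sampling_rng: np.random.Generator | None = None,
) -> RawHeartRateLog:
    """Sample the latent minute process at irregular (exponential) intervals.

    Event times are a Poisson process with mean interval
    ``hr_sampling_interval_mean`` seconds, rounded to whole seconds with a
    1-second floor so timestamps stay strictly increasing. The BPM at an
    event is the linear interpolant of the minute process at that instant.
    """
    if process_rng is None or sampling_rng is None:
        streams = _streams(profile)
        process_rng = process_rng or streams["hr_process"]
        sampling_rng = sampling_rng or streams["hr_sampling"]
    minute_hr = heart_rate_minute_process(profile, episodes, rng=process_rng)

    total_seconds = profile.n_minutes * 60
    # draw enough gaps in one shot, then trim to the recording span
    n_expect = int(total_seconds / profile.hr_sampling_interval_mean * 1.25) + 50
    gaps = sampling_rng.exponential(profile.hr_sampling_interval_mean, size=n_expect)
    while gaps.sum() < total_seconds:
        gaps = np.concatenate(
            [gaps, sampling_rng.exponential(profile.hr_sampling_interval_mean, size=n_expect)]
        )
    gaps = np.maximum(1, np.round(gaps)).astype(np.int64)
    t = np.cumsum(gaps)
    t = t[t < total_seconds]
    bpm = np.interp(t / 60.0, np.arange(profile.n_minutes), minute_hr)
    times = profile.start + pd.to_timedelta(t, unit="s")
    return RawHeartRateLog(times=pd.DatetimeIndex(times), bpm=bpm)


def simulate_user(
    profile: UserProfile,
) -> tuple[RawHeartRateLog, list[ActivityEpisode]]:
    """Simulate one user's full raw recording from a single seed."""
    streams = _streams(profile)
    episodes = simulate_episodes(profile, rng=streams["episodes"])
    hr_log = simulate_heart_rate(
        profile,
        episodes,
        process_rng=streams["hr_process"],
        sampling_rng=streams["hr_sampling"],
    )
    return hr_log, episodes
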