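"""Deterministic reinforcement-schedule state machines.

Scores ordered response streams under the schedules used in DRL operant
experiments:

* **DRL-N** — a response is reinforced iff its inter-response time (IRT)
  strictly exceeds the criterion (e.g. DRL15 = IRT > 15 s).
* **Adjusting DRL** — shaping from a short criterion (2 s) up to the target:
  the criterion is multiplied by (1 + 0.0075) after every reinforced response
  and saturates at the target; the final value carries over to the next
  session.
* **Progressive ratio (PR)** — the response cost of each successive reinforcer
  follows an increasing progression; the session ends at the first pause of
  15 min (the breakpoint).

Convention: the first response's IRT is measured from session start (time 0),
matching the "timer since last event" behaviour of operant chambers.  IRTs are
response-to-response; reinforcer delivery does not reset a separate timer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "ScheduleKind",
    "Group",
    "Reinforcer",
    "Day",
    "ScheduleConfig",
    "SessionEvents",
    "PRResult",
    "AdjustingDRLResult",
    "score_drl_session",
    "run_adjusting_drl",
    "reinforcers_to_reach",
    "run_progressive_ratio",
    "drl15",
    "drl",
]


class ScheduleKind(str, Enum):
    DRL = "DRL"
    ADJUSTING_DRL = "ADJUSTING_DRL"
    PR = "PR"


class Group(str, Enum):
    CIE = "CIE"
    CON = "CON"


class Reinforcer(str, Enum):
    SUCROSE = "SUCROSE"
    ETHANOL = "ETHANOL"


class Day(str, Enum):
    MON = "Mon"
    TUE = "Tue"
    WED = "Wed"
    THU = "Thu"
    FRI = "Fri"


#: Test-scaffold PR progression (the experimental progression is lab-specific
#: and must be supplied explicitly for real data).
DEFAULT_PR_PROGRESSION = (1, 2, 4, 6, 9, 12, 15, 20, 25, 32, 40, 50)


@dataclass(frozen=True)
class ScheduleConfig:
    """Configuration of one reinforcement schedule."""

    kind: ScheduleKind
    criterion_s: float = 15.0
    session_duration_s: float = 1800.0
    increment_fraction: float = 0.0075
    start_criterion_s: float = 2.0
    pr_progression: tuple[int, ...] = DEFAULT_PR_PROGRESSION
    pr_hang_limit_s: float = 900.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ScheduleKind(self.kind))
        object.__setattr__(self, "pr_progression", tuple(self.pr_progression))
        if not self.criterion_s > 0:
            raise InvalidParameterError("criterion_s must be positive")
        if not self.session_duration_s > 0:
            raise InvalidParameterError("session_duration_s must be positive")
        if not (0.0 < self.increment_fraction < 1.0):
            raise InvalidParameterError("increment_fraction must be in (0, 1)")
        if not self.start_criterion_s > 0:
            raise InvalidParameterError("start_criterion_s must be positive")
        if self.kind is ScheduleKind.PR:
            prog = self.pr_progression
            if not prog:
                raise InvalidParameterError("pr_progression must be non-empty")
            if any(r <= 0 for r in prog) or any(
                b < a for a, b in zip(prog, prog[1:])
            ):
                raise InvalidParameterError(
                    "pr_progression must be strictly positive and non-decreasing"
                )
            if not self.pr_hang_limit_s > 0:
                raise InvalidParameterError("pr_hang_limit_s must be positive")


def drl(criterion_s: float, session_duration_s: float = 1800.0) -> ScheduleConfig:
    """Convenience constructor for a plain DRL schedule."""
    return ScheduleConfig(
        kind=ScheduleKind.DRL,
        criterion_s=criterion_s,
        session_duration_s=session_duration_s,
    )


def drl15() -> ScheduleConfig:
    """The standard DRL15 30-min session."""
    return drl(15.0)


@dataclass(frozen=True)
class SessionEvents:
    """One session's ordered responses, reinforcement flags and metadata."""

    subject_id: str
    group: Group
    reinforcer_type: Reinforcer
    day: Day
    week_index: int
    response_times_s: np.ndarray
    reinforced_flags: np.ndarray
    schedule: ScheduleConfig

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "reinforcer_type", Reinforcer(self.reinforcer_type))
        object.__setattr__(self, "day", Day(self.day))
        times = np.asarray(self.response_times_s, dtype=float)
        flags = np.asarray(self.reinforced_flags, dtype=bool)
        object.__setattr__(self, "response_times_s", times)
        object.__setattr__(self, "reinforced_flags", flags)
        if times.size != flags.size:
            raise InvalidInputError("response_times_s and reinforced_flags differ in length")
        _validate_times(times)
        if times.size and times[-1] > self.schedule.session_duration_s:
            raise InvalidInputError("response time exceeds session duration")

    @property
    def n_responses(self) -> int:
        return int(self.response_times_s.size)

    @property
    def n_reinforcers(self) -> int:
        return int(self.reinforced_flags.sum())


class AdjustingDRLResult(NamedTuple):
    criterion_trajectory: np.ndarray  # criterion in force for each response
    final_criterion_s: float  # carries over to the next session
    reinforced_flags: np.ndarray


@dataclass(frozen=True)
class PRResult:
    """Outcome of a progressive-ratio session."""

    reinforcers_earned: int
    breakpoint_ratio: int  # last completed ratio requirement (0 if none)
    total_responses: int
    cumulative_curve: np.ndarray  # cumulative presses at each 1-min boundary
    termination_time_s: float


def _validate_times(times: np.ndarray) -> None:
    if times.size == 0:
        return
    if not np.all(np.isfinite(times)):
        raise InvalidInputError("response times must be finite")
    if times[0] < 0:
        raise InvalidInputError("response times must be non-negative")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise InvalidInputError("response times must be strictly increasing")


def score_drl_session(
    response_times: Sequence[float], criterion_s: float
) -> tuple[np.ndarray, int, int]:
    """Score a response stream under DRL: reinforce iff IRT > criterion.

    The first response's IRT is its latency from session start.  Returns
    ``(reinforced_flags, n_responses, n_reinforcers)``.
    """
    if not criterion_s >= 0:
        raise InvalidParameterError("criterion_s must be non-negative")
    times = np.asarray(response_times, dtype=float)
    _validate_times(times)
    if times.size == 0:
        return np.zeros(0, dtype=bool), 0, 0
    irts = np.diff(times, prepend=0.0)
    flags = irts > criterion_s
    return flags, int(times.size), int(flags.sum())


def run_adjusting_drl(
    response_times: Sequence[float], cfg: ScheduleConfig
) -> AdjustingDRLResult:
    """Score a stream under the adjusting DRL used to shape 2 s -> 15 s.

    Each response is evaluated against the criterion in force; after every
    reinforced response the criterion is multiplied by
    ``1 + increment_fraction`` and capped at ``criterion_s``.  The final
    criterion is returned for carry-over when the target was not reached
    within the session.
    """
    if ScheduleKind(cfg.kind) is not ScheduleKind.ADJUSTING_DRL:
        raise InvalidParameterError("cfg.kind must be ADJUSTING_DRL")
    times = np.asarray(response_times, dtype=float)
    _validate_times(times)
    criterion = float(cfg.start_criterion_s)
    trajectory = np.empty(times.size)
    flags = np.zeros(times.size, dtype=bool)
    prev = 0.0
    for i, t in enumerate(times):
        trajectory[i] = criterion
        if t - prev > criterion:
            flags[i] = True
            criterion = min(criterion * (1.0 + cfg.increment_fraction), cfg.criterion_s)
        prev = t
    return AdjustingDRLResult(trajectory, criterion, flags)


def reinforcers_to_reach(
    start_s: float, target_s: float, increment_fraction: float
) -> int:
    """Smallest k with start * (1 + f)^k >= target (closed form, exact)."""
    if not (start_s > 0 and increment_fraction > 0):
        raise InvalidInputError("start_s and increment_fraction must be positive")
    if target_s < start_s:
        raise InvalidInputError("target_s must be >= start_s")
    if target_s == start_s:
        return 0
    growth = 1.0 + increment_fraction
    k = max(int(math.ceil(math.log(target_s / start_s) / math.log(growth))), 0)
    # guard the closed form against floating-point edge effects
    while start_s * growth**k < target_s:
        k += 1
    while k > 0 and start_s * growth ** (k - 1) >= target_s:
        k -= 1
    return k


def run_progressive_ratio(
    press_times: Sequence[float], cfg: ScheduleConfig
) -> PRResult:
    """Run a progressive-ratio session over an ordered lever-press stream.

    A reinforcer is delivered whenever the presses accumulated since the last
    reinforcer meet the current progression entry.  The session terminates at
    the first inter-press gap of at least ``pr_hang_limit_s`` (measured between
    consecutive presses and from session start to the first press); presses
    after the gap are discarded.
    """
    if ScheduleKind(cfg.kind) is not ScheduleKind.PR:
        raise InvalidParameterError("cfg.kind must be PR")
    times = np.asarray(press_times, dtype=float)
    _validate_times(times)

    hang = cfg.pr_hang_limit_s
    prev = 0.0
    counted: list[float] = []
    terminated = False
    for t in times:
        if t - prev >= hang:
            terminated = True
            break
        counted.append(float(t))
        prev = t

    progression = cfg.pr_progression
    reinforcers = 0
    since_last = 0
    for _ in counted:
        since_last += 1
        if reinforcers < len(progression) and since_last >= progression[reinforcers]:
            reinforcers += 1
            since_last = 0

    total = len(counted)
    if terminated or times.size > total:
        termination = prev + hang
    else:
        termination = counted[-1] if counted else 0.0
    n_bins = max(int(math.ceil(termination / 60.0)), 1)
    counts, _ = np.histogram(counted, bins=n_bins, range=(0.0, n_bins * 60.0))
    curve = np.cumsum(counts)
    return PRResult(
        reinforcers_earned=reinforcers,
        breakpoint_ratio=progression[reinforcers - 1] if reinforcers else 0,
        total_responses=total,
        cumulative_curve=curve,
        termination_time_s=float(termination),
    )
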