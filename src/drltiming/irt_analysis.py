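"""Descriptive IRT analysis: efficiency, binned distributions, weekly averages.

The efficiency of reinforcement, 100 * reinforcers / responses, is the
session-level index of response inhibition (higher efficiency = better
inhibition, lower impulsivity).  IRT distributions are summarised as percent
of responses per 0.5-s bin over 120 bins (0-60 s) with an explicit overflow
count for longer pauses.  Weekly statistics average the Tuesday-Thursday
sessions only: Mondays follow the weekend break and Fridays follow the
blood-draw stress, so both are excluded by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyDistributionError,
    InvalidInputError,
    UndefinedEfficiencyError,
)
from .schedule import Day, SessionEvents

__all__ = [
    "BinnedIRT",
    "WeeklySummary",
    "ChallengeRecord",
    "compute_irts",
    "efficiency",
    "bin_irt_distribution",
    "weekly_summary",
    "stability_check",
    "challenge_comparison",
    "DEFAULT_INCLUDED_DAYS",
]

logger = logging.getLogger(__name__)

DEFAULT_INCLUDED_DAYS = frozenset({Day.TUE, Day.WED, Day.THU})


def compute_irts(session: SessionEvents) -> np.ndarray:
    """Inter-response times of a session, seconds.

    The first element is the latency of the first response from session start,
    consistently with how the schedule engine scores it.
    """
    times = session.response_times_s
    if times.size == 0:
        return np.zeros(0)
    return np.diff(times, prepend=0.0)


def efficiency(session: SessionEvents) -> float:
    """Efficiency of reinforcement: 100 * reinforcers / responses."""
    if session.n_responses == 0:
        raise UndefinedEfficiencyError(
            f"session {session.subject_id} week {session.week_index} "
            f"{session.day.value} has zero responses"
        )
    return 100.0 * session.n_reinforcers / session.n_responses


@dataclass(frozen=True)
class BinnedIRT:
    """Percent of responses per 0.5-s IRT bin (120 bins, 0-60 s)."""

    percent_per_bin: np.ndarray
    n_irts: int
    overflow_count: int
    bin_width_s: float = 0.5

    @property
    def n_bins(self) -> int:
        return int(self.percent_per_bin.size)

    @property
    def bin_edges_s(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width_s


def bin_irt_distribution(
    irts: Sequence[float], bin_width_s: float = 0.5, n_bins: int = 120
) -> BinnedIRT:
    """Bin IRTs into half-open [k*w, (k+1)*w) bins as percent of all IRTs.

    IRTs at or beyond ``n_bins * bin_width_s`` (60 s by default) are counted
    in ``overflow_count``; percentages are relative to the total including
    overflow, so the 120 bins sum to <= 100.
    """
    x = np.asarray(irts, dtype=float)
    if x.size == 0:
        raise EmptyDistributionError("cannot bin an empty IRT sample")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise InvalidInputError("IRTs must be finite and non-negative")
    limit = n_bins * bin_width_s
    overflow = int(np.sum(x >= limit))
    counts, _ = np.histogram(x[x < limit], bins=n_bins, range=(0.0, limit))
    return BinnedIRT(
        percent_per_bin=100.0 * counts / x.size,
        n_irts=int(x.size),
        overflow_count=overflow,
        bin_width_s=bin_width_s,
    )


@dataclass(frozen=True)
class WeeklySummary:
    """Per-subject weekly means over the included (Tue-Thu) sessions."""

    subject_id: str
    week_index: int
    mean_efficiency: float  # percent; NaN when no included session qualifies
    mean_reinforcers: float  # per session; NaN likewise
    sessions_used: tuple[Day, ...]


def weekly_summary(
    sessions: Sequence[SessionEvents],
    included_days: Iterable[Day] = DEFAULT_INCLUDED_DAYS,
) -> WeeklySummary:
    """Average efficiency and reinforcers over one subject-week.

    Only sessions on ``included_days`` enter the means.  Zero-response
    sessions have undefined efficiency and are excluded with a warning; if no
    included session remains, the means are NaN (an explicit missing-value
    marker, never a silent zero).
    """
    if not sessions:
        raise InvalidInputError("weekly_summary needs at least one session")
    subjects = {s.subject_id for s in sessions}
    weeks = {s.week_index for s in sessions}
    if len(subjects) > 1 or len(weeks) > 1:
        raise InvalidInputError(
            f"sessions span multiple subjects/weeks: {subjects} x {weeks}"
        )
    included = frozenset(Day(d) for d in included_days)
    effs: list[float] = []
    reinf: list[int] = []
    used: list[Day] = []
    for s in sessions:
        if s.day not in included:
            continue
        try:
            effs.append(efficiency(s))
        except UndefinedEfficiencyError:
            logger.warning(
                "excluding zero-response session %s week %s %s from weekly mean",
                s.subject_id,
                s.week_index,
                s.day.value,
            )
            continue
        reinf.append(s.n_reinforcers)
        used.append(s.day)
    if not effs:
        logger.warning(
            "subject %s week %s has no usable Tue-Thu session; weekly mean is missing",
            sessions[0].subject_id,
            sessions[0].week_index,
        )
    return WeeklySummary(
        subject_id=sessions[0].subject_id,
        week_index=sessions[0].week_index,
        mean_efficiency=float(np.mean(effs)) if effs else math.nan,
        mean_reinforcers=float(np.mean(reinf)) if reinf else math.nan,
        sessions_used=tuple(used),
    )


def stability_check(
    efficiencies: Sequence[float], window: int = 3, threshold: float = 0.10
) -> bool | None:
    """Has performance stabilised: <10% variation over 3 consecutive sessions?

    "Variation" is the range of the window divided by its mean.  Returns
    ``None`` (not assessable) when fewer than ``window`` sessions are given.
    """
    if window < 2:
        raise InvalidInputError("window must be >= 2")
    e = np.asarray(efficiencies, dtype=float)
    if e.size < window:
        return None
    for i in range(e.size - window + 1):
        w = e[i : i + window]
        mean = np.mean(w)
        if mean > 0 and (np.max(w) - np.min(w)) / mean < threshold:
            return True
    return False


@dataclass(frozen=True)
class ChallengeRecord:
    """Paired weekly-DRL15 vs DRL20-challenge comparison for one subject."""

    subject_id: str
    drl15_mean_efficiency: float
    challenge_efficiency: float
    efficiency_change: float  # challenge - weekly mean (negative = drop)
    drl15_mean_reinforcers: float
    challenge_reinforcers: int


def challenge_comparison(
    week_sessions: Sequence[SessionEvents],
    challenge_session: SessionEvents,
    included_days: Iterable[Day] = DEFAULT_INCLUDED_DAYS,
) -> ChallengeRecord:
    """Compare a subject's weekly DRL15 average against the DRL20 challenge.

    The cognitive-load challenge abruptly raises the criterion for one
    session; the paired record feeds downstream group statistics.
    """
    if challenge_session is None:
        raise InvalidInputError("challenge_session is required")
    weekly = weekly_summary(week_sessions, included_days)
    if challenge_session.subject_id != weekly.subject_id:
        raise InvalidInputError("challenge session belongs to a different subject")
    chall_eff = efficiency(challenge_session)
    return ChallengeRecord(
        subject_id=weekly.subject_id,
        drl15_mean_efficiency=weekly.mean_efficiency,
        challenge_efficiency=chall_eff,
        efficiency_change=chall_eff - weekly.mean_efficiency,
        drl15_mean_reinforcers=weekly.mean_reinforcers,
        challenge_reinforcers=challenge_session.n_reinforcers,
    )
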