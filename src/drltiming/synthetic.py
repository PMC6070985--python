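"""Generative model of DRL operant sessions and CIE-vs-control cohorts.

Sessions are simulated as renewal processes: IRTs are drawn i.i.d. from the
TR mixture (:mod:`drltiming.tr_model`), cumulatively summed into response
times, truncated at the session end, and scored by the schedule engine.

Cohorts emulate the within-subjects vapor-exposure design: one prevapor week
(week 0), six weeks of chronic intermittent ethanol exposure (CIE, weeks 1-6)
and five weeks of forced abstinence (weeks 7-11), five sessions per week
(Mon-Fri), with n = 8 subjects per group.  Control subjects keep the baseline
parameter vector throughout; CIE subjects receive week-scheduled multipliers
on the burst decay rate L (fewer/faster-decaying bursts when L rises, more
persistent bursting when it falls), the timed mean N*c (rightward IRT shift)
and the timed proportion p.  The default effect — L halved and N*c shifted
right by 5% in late abstinence (weeks 9-11) — encodes the direction of the
abstinence phenotype: a lower burst decay rate and a rightward shift of the
timed IRTs in the CIE group.

Every subject owns one pseudo-random stream derived from (cohort seed, group,
subject index), so generation is reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError
from .schedule import (
    Day,
    Group,
    PRResult,
    Reinforcer,
    ScheduleConfig,
    ScheduleKind,
    SessionEvents,
    drl15,
    run_adjusting_drl,
    run_progressive_ratio,
    score_drl_session,
)
from .tr_model import TRParams

__all__ = [
    "DEFAULT_BASELINE_PARAMS",
    "DEFAULT_CIE_EFFECTS",
    "CieEffect",
    "CohortSpec",
    "sample_irt",
    "sample_irts",
    "simulate_session",
    "simulate_pr_session",
    "simulate_cohort",
]

#: Synthetic baseline parameter vector: a competent DRL15 responder whose
#: derived proportions (timed 0.70, burst 0.18, long 0.12) and response
#: threshold (theta ~ 1.07) sit in the empirically typical range.
DEFAULT_BASELINE_PARAMS = TRParams(
    p=0.7, q=0.6, N=6.0, c=2.67, L=2.0, Lprime=0.05, delta=0.3
)

WEEKDAYS = (Day.MON, Day.TUE, Day.WED, Day.THU, Day.FRI)

#: Week phases of the vapor-exposure timeline.
PREVAPOR_WEEK = 0
CIE_WEEKS = tuple(range(1, 7))
ABSTINENCE_WEEKS = tuple(range(7, 12))


@dataclass(frozen=True)
class CieEffect:
    """Multiplicative group effect applied to CIE subjects in one week."""

    L_mult: float = 1.0
    nc_mult: float = 1.0  # applied to the gamma scale c, shifting the timed mean
    p_mult: float = 1.0

    def __post_init__(self) -> None:
        for name in ("L_mult", "nc_mult", "p_mult"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")

    def apply(self, params: TRParams) -> TRParams:
        return params.replace(
            p=min(params.p * self.p_mult, 1.0),
            c=params.c * self.nc_mult,
            L=params.L * self.L_mult,
        )


#: Late-abstinence phenotype: burst decay halved, timed mean +5%.
DEFAULT_CIE_EFFECTS: dict[int, CieEffect] = {
    week: CieEffect(L_mult=0.5, nc_mult=1.05) for week in (9, 10, 11)
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort: subjects x groups x weeks x sessions."""

    n_per_group: int = 8
    baseline_params: TRParams = DEFAULT_BASELINE_PARAMS
    cie_effects: Mapping[int, CieEffect] = field(
        default_factory=lambda: dict(DEFAULT_CIE_EFFECTS)
    )
    weeks: tuple[int, ...] = tuple(range(12))
    sessions_per_week: int = 5
    schedule: ScheduleConfig = field(default_factory=drl15)
    reinforcer_type: Reinforcer = Reinforcer.ETHANOL
    subject_cv: float = 0.0  # log-normal sigma for per-subject (N*c, L) scatter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise InvalidParameterError("n_per_group must be >= 1")
        if not (1 <= self.sessions_per_week <= len(WEEKDAYS)):
            raise InvalidParameterError("sessions_per_week must be in 1..5")
        if self.subject_cv < 0:
            raise InvalidParameterError("subject_cv must be >= 0")
        object.__setattr__(self, "weeks", tuple(self.weeks))


def sample_irts(params: TRParams, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw ``size`` i.i.d. IRTs from the TR mixture."""
    params.validate()
    weights = np.array(params.proportions)
    component = rng.choice(3, size=size, p=weights)
    out = np.empty(size)
    n_timed = int(np.sum(component == 0))
    n_burst = int(np.sum(component == 1))
    n_long = size - n_timed - n_burst
    out[component == 0] = rng.gamma(params.N, params.c, size=n_timed)
    out[component == 1] = rng.exponential(1.0 / params.L, size=n_burst)
    out[component == 2] = rng.exponential(1.0 / params.Lprime, size=n_long)
    return params.delta + out


def sample_irt(params: TRParams, rng: np.random.Generator) -> float:
    """Draw a single IRT from the TR mixture."""
    return float(sample_irts(params, rng, 1)[0])


def _renewal_times(
    params: TRParams, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative response times of the renewal process, truncated at the end."""
    chunk = max(int(2 * duration_s / max(params.mean_irt_s, 1e-6)), 16)
    times = np.cumsum(sample_irts(params, rng, chunk))
    while times.size == 0 or times[-1] <= duration_s:
        more = times[-1] if times.size else 0.0
        extra = more + np.cumsum(sample_irts(params, rng, chunk))
        times = np.concatenate([times, extra])
    return times[times <= duration_s]


def simulate_session(
    params: TRParams,
    schedule: ScheduleConfig,
    rng: np.random.Generator,
    *,
    subject_id: str = "S00",
    group: Group = Group.CON,
    reinforcer_type: Reinforcer = Reinforcer.SUCROSE,
    day: Day = Day.TUE,
    week_index: int = 0,
) -> SessionEvents:
    """Simulate one DRL (or adjusting-DRL) session and score it."""
    kind = ScheduleKind(schedule.kind)
    if kind is ScheduleKind.PR:
        raise InvalidParameterError("use simulate_pr_session for PR schedules")
    times = _renewal_times(params, schedule.session_duration_s, rng)
    if kind is ScheduleKind.DRL:
        flags, _, _ = score_drl_session(times, schedule.criterion_s)
    else:
        flags = run_adjusting_drl(times, schedule).reinforced_flags
    return SessionEvents(
        subject_id=subject_id,
        group=group,
        reinforcer_type=reinforcer_type,
        day=day,
        week_index=week_index,
        response_times_s=times,
        reinforced_flags=flags,
        schedule=schedule,
    )


def simulate_pr_session(
    params: TRParams,
    cfg: ScheduleConfig,
    rng: np.random.Generator,
    max_duration_s: float = 7200.0,
) -> tuple[np.ndarray, PRResult]:
    """Simulate lever pressing under a progressive-ratio schedule.

    The press stream is the same renewal process; the PR state machine then
    applies the escalating ratio requirement and the 15-min breakpoint rule.
    """
    presses = _renewal_times(params, max_duration_s, rng)
    return presses, run_progressive_ratio(presses, cfg)


def _subject_params(
    spec: CohortSpec, group: Group, subject_rng: np.random.Generator
) -> TRParams:
    """Baseline parameters with optional per-subject log-normal scatter."""
    params = spec.baseline_params
    if spec.subject_cv > 0:
        nc_jitter, l_jitter = np.exp(
            subject_rng.normal(0.0, spec.subject_cv, size=2)
        )
        params = params.replace(c=params.c * nc_jitter, L=params.L * l_jitter)
    return params


def simulate_cohort(spec: CohortSpec) -> list[SessionEvents]:
    """Simulate every session of a cohort, ordered by group/subject/week/day.

    Control subjects use the (possibly subject-jittered) baseline parameters
    in every week; CIE subjects apply ``spec.cie_effects[week]`` where
    scheduled.  One random stream per subject, spawned from
    ``(seed, group index, subject index)``.
    """
    sessions: list[SessionEvents] = []
    for g_idx, group in enumerate((Group.CON, Group.CIE)):
        for s_idx in range(spec.n_per_group):
            subject_id = f"{group.value}{s_idx + 1:02d}"
            rng = np.random.default_rng([spec.seed, g_idx, s_idx])
            base = _subject_params(spec, group, rng)
            for week in spec.weeks:
                params = base
                if group is Group.CIE and week in spec.cie_effects:
                    params = spec.cie_effects[week].apply(base)
                for day in WEEKDAYS[: spec.sessions_per_week]:
                    sessions.append(
                        simulate_session(
                            params,
                            spec.schedule,
                            rng,
                            subject_id=subject_id,
                            group=group,
                            reinforcer_type=spec.reinforcer_type,
                            day=day,
                            week_index=week,
                        )
                    )
    return sessions
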