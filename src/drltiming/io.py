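"""Event-log and result-table IO, configuration parsing, and the pipeline.

The on-disk interchange format is a plain CSV event log, one row per event::

    subject_id, group, reinforcer_type, week, day, event_time_s, event_kind

with ``event_kind`` in {response, reinforcer} and times in seconds at 3-decimal
fixed precision.  A reinforcer row shares its timestamp with the response that
earned it.  All result tables are plain CSV; every pipeline run writes a JSON
manifest (config hash, seed, library versions) so outputs are attributable
and reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import InvalidInputError
from .irt_analysis import (
    DEFAULT_INCLUDED_DAYS,
    bin_irt_distribution,
    compute_irts,
    efficiency,
    weekly_summary,
)
from .schedule import (
    Day,
    Group,
    Reinforcer,
    ScheduleConfig,
    ScheduleKind,
    SessionEvents,
    drl15,
)
from .stats import effect_size_from_t, ks_two_sample
from .synthetic import (
    CieEffect,
    CohortSpec,
    simulate_cohort,
    simulate_pr_session,
)
from .tr_model import FitMode, TRParams, fit_tr_model

__all__ = [
    "EVENT_LOG_COLUMNS",
    "write_event_log",
    "read_event_log",
    "session_metrics_table",
    "weekly_summary_table",
    "binned_irt_table",
    "fit_table",
    "write_manifest",
    "parse_cohort_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

EVENT_LOG_COLUMNS = (
    "subject_id",
    "group",
    "reinforcer_type",
    "week",
    "day",
    "event_time_s",
    "event_kind",
)

_DAY_ORDER = {d.value: i for i, d in enumerate(Day)}


def write_event_log(sessions: Sequence[SessionEvents], path: str | Path) -> None:
    """Write sessions as the CSV event log (3-decimal timestamps)."""
    rows: list[tuple] = []
    for s in sessions:
        for t, reinforced in zip(s.response_times_s, s.reinforced_flags):
            base = (
                s.subject_id,
                s.group.value,
                s.reinforcer_type.value,
                s.week_index,
                s.day.value,
                f"{t:.3f}",
            )
            rows.append(base + ("response",))
            if reinforced:
                rows.append(base + ("reinforcer",))
    pd.DataFrame(rows, columns=EVENT_LOG_COLUMNS).to_csv(path, index=False)


def read_event_log(
    path: str | Path, schedule: ScheduleConfig | None = None
) -> list[SessionEvents]:
    """Read and validate an event-log CSV into SessionEvents objects.

    ``schedule`` attaches schedule metadata (the log itself carries none);
    defaults to DRL15.  Malformed rows are reported with their file line
    numbers (header = line 1).
    """
    schedule = schedule or drl15()
    df = pd.read_csv(path, dtype={"day": str, "event_kind": str})
    if tuple(df.columns) != EVENT_LOG_COLUMNS:
        raise InvalidInputError(
            f"event log header mismatch: expected {EVENT_LOG_COLUMNS}, "
            f"got {tuple(df.columns)}"
        )
    if df.empty:
        logger.warning("event log %s is empty", path)
        return []
    bad_kind = df[~df["event_kind"].isin(["response", "reinforcer"])]
    if not bad_kind.empty:
        raise InvalidInputError(
            f"unknown event_kind at lines {[i + 2 for i in bad_kind.index[:5]]}"
        )
    sessions: list[SessionEvents] = []
    keys = ["subject_id", "group", "reinforcer_type", "week", "day"]
    for (subj, group, rtype, week, day), g in df.groupby(keys, sort=True):
        g = g.sort_index()
        # millisecond integer timestamps avoid float-equality pitfalls
        ms = np.round(g["event_time_s"].to_numpy(dtype=float) * 1000).astype(np.int64)
        is_resp = (g["event_kind"] == "response").to_numpy()
        if not is_resp[0]:
            raise InvalidInputError(
                f"reinforcer precedes any response at line {g.index[0] + 2} "
                f"(subject {subj}, week {week}, {day})"
            )
        resp_ms = ms[is_resp]
        if np.any(np.diff(resp_ms) <= 0):
            offender = int(np.argmax(np.diff(resp_ms) <= 0)) + 1
            line = g.index[is_resp.nonzero()[0][offender]] + 2
            raise InvalidInputError(
                f"non-monotone response times at line {line} "
                f"(subject {subj}, week {week}, {day})"
            )
        reinf_ms = set(ms[~is_resp].tolist())
        unmatched = reinf_ms - set(resp_ms.tolist())
        if unmatched:
            raise InvalidInputError(
                f"reinforcer without a matching response (subject {subj}, "
                f"week {week}, {day}): times {sorted(unmatched)[:5]} ms"
            )
        flags = np.isin(resp_ms, list(reinf_ms))
        sessions.append(
            SessionEvents(
                subject_id=str(subj),
                group=Group(group),
                reinforcer_type=Reinforcer(rtype),
                day=Day(day),
                week_index=int(week),
                response_times_s=resp_ms / 1000.0,
                reinforced_flags=flags,
                schedule=schedule,
            )
        )
    sessions.sort(
        key=lambda s: (s.group.value, s.subject_id, s.week_index, _DAY_ORDER[s.day.value])
    )
    return sessions


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def session_metrics_table(sessions: Sequence[SessionEvents]) -> pd.DataFrame:
    """Per-session responses, reinforcers and efficiency (NaN when undefined)."""
    rows = []
    for s in sessions:
        eff = 100.0 * s.n_reinforcers / s.n_responses if s.n_responses else np.nan
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group.value,
                "week": s.week_index,
                "day": s.day.value,
                "n_responses": s.n_responses,
                "n_reinforcers": s.n_reinforcers,
                "efficiency": eff,
            }
        )
    return pd.DataFrame(rows)


def _grouped_by_subject_week(
    sessions: Sequence[SessionEvents],
) -> dict[tuple[str, int], list[SessionEvents]]:
    grouped: dict[tuple[str, int], list[SessionEvents]] = {}
    for s in sessions:
        grouped.setdefault((s.subject_id, s.week_index), []).append(s)
    return grouped


def weekly_summary_table(
    sessions: Sequence[SessionEvents],
    included_days: frozenset[Day] = DEFAULT_INCLUDED_DAYS,
) -> pd.DataFrame:
    """Weekly Tue-Thu averages per subject (long format)."""
    rows = []
    for (subj, week), group_sessions in sorted(_grouped_by_subject_week(sessions).items()):
        ws = weekly_summary(group_sessions, included_days)
        rows.append(
            {
                "subject_id": subj,
                "group": group_sessions[0].group.value,
                "week": week,
                "mean_efficiency": ws.mean_efficiency,
                "mean_reinforcers": ws.mean_reinforcers,
                "n_sessions_used": len(ws.sessions_used),
            }
        )
    return pd.DataFrame(rows)


def binned_irt_table(
    sessions: Sequence[SessionEvents],
    included_days: frozenset[Day] = DEFAULT_INCLUDED_DAYS,
) -> pd.DataFrame:
    """Pooled 0.5-s binned IRT distribution per subject-week (long format)."""
    rows = []
    for (subj, week), group_sessions in sorted(_grouped_by_subject_week(sessions).items()):
        irts = np.concatenate(
            [compute_irts(s) for s in group_sessions if s.day in included_days]
            or [np.zeros(0)]
        )
        if irts.size == 0:
            continue
        binned = bin_irt_distribution(irts)
        for k, pct in enumerate(binned.percent_per_bin):
            rows.append(
                {
                    "subject_id": subj,
                    "group": group_sessions[0].group.value,
                    "week": week,
                    "bin_lo_s": k * binned.bin_width_s,
                    "percent": pct,
                }
            )
    return pd.DataFrame(rows)


def fit_table(
    sessions: Sequence[SessionEvents],
    mode: FitMode | str = FitMode.MLE,
    weeks: Sequence[int] | None = None,
    included_days: frozenset[Day] = DEFAULT_INCLUDED_DAYS,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the TR model per subject-week on pooled Tue-Thu IRTs.

    Returns one row per subject-week mirroring the standard parameter table:
    timed proportion, response threshold, burst proportion and decay, long
    component, Weber fraction, shift, objective and convergence flag.
    """
    rows = []
    for (subj, week), group_sessions in sorted(_grouped_by_subject_week(sessions).items()):
        if weeks is not None and week not in weeks:
            continue
        irts = [compute_irts(s) for s in group_sessions if s.day in included_days]
        pooled = np.concatenate(irts) if irts else np.zeros(0)
        if pooled.size < 2:
            logger.warning("skipping fit for %s week %s: too few IRTs", subj, week)
            continue
        criterion = group_sessions[0].schedule.criterion_s
        fit = fit_tr_model(pooled, mode=mode, criterion_s=criterion, seed=seed)
        d = fit.derived
        rows.append(
            {
                "subject_id": subj,
                "group": group_sessions[0].group.value,
                "week": week,
                "n_irts": fit.n_irts,
                "prop_timed": d["prop_timed"],
                "theta": d["theta"],
                "prop_burst": d["prop_burst"],
                "L": fit.params.L,
                "prop_long": d["prop_long"],
                "Lprime": fit.params.Lprime,
                "omega": d["omega"],
                "delta": fit.params.delta,
                "objective": fit.objective_value,
                "mode": fit.mode.value,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Config / manifest
# ---------------------------------------------------------------------------

_COHORT_KEYS = {
    "n_per_group",
    "seed",
    "weeks",
    "sessions_per_week",
    "subject_cv",
    "reinforcer_type",
    "baseline_params",
    "cie_effects",
    "schedule",
}
_PARAM_KEYS = {"p", "q", "N", "c", "L", "Lprime", "delta"}
_EFFECT_KEYS = {"L_mult", "nc_mult", "p_mult"}
_SCHEDULE_KEYS = {
    "kind",
    "criterion_s",
    "session_duration_s",
    "increment_fraction",
    "start_criterion_s",
    "pr_progression",
    "pr_hang_limit_s",
}


def _check_keys(block: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise InvalidInputError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def parse_cohort_config(config: Mapping[str, Any]) -> CohortSpec:
    """Build a CohortSpec from a config mapping; unknown keys are rejected."""
    _check_keys(config, _COHORT_KEYS, "cohort")
    kwargs: dict[str, Any] = {}
    for key in ("n_per_group", "seed", "sessions_per_week"):
        if key in config:
            kwargs[key] = int(config[key])
    if "weeks" in config:
        kwargs["weeks"] = tuple(int(w) for w in config["weeks"])
    if "subject_cv" in config:
        kwargs["subject_cv"] = float(config["subject_cv"])
    if "reinforcer_type" in config:
        kwargs["reinforcer_type"] = Reinforcer(config["reinforcer_type"])
    if "baseline_params" in config:
        _check_keys(config["baseline_params"], _PARAM_KEYS, "baseline_params")
        kwargs["baseline_params"] = TRParams(**config["baseline_params"])
    if "cie_effects" in config:
        effects = {}
        for week, block in config["cie_effects"].items():
            _check_keys(block, _EFFECT_KEYS, f"cie_effects[{week}]")
            effects[int(week)] = CieEffect(**block)
        kwargs["cie_effects"] = effects
    if "schedule" in config:
        _check_keys(config["schedule"], _SCHEDULE_KEYS, "schedule")
        kwargs["schedule"] = ScheduleConfig(**config["schedule"])
    return CohortSpec(**kwargs)


def _config_dict(spec: CohortSpec) -> dict[str, Any]:
    d = dataclasses.asdict(spec)
    d["reinforcer_type"] = spec.reinforcer_type.value
    d["schedule"]["kind"] = spec.schedule.kind.value
    d["schedule"]["pr_progression"] = list(spec.schedule.pr_progression)
    d["weeks"] = list(spec.weeks)
    d["cie_effects"] = {str(k): dataclasses.asdict(v) for k, v in spec.cie_effects.items()}
    return d


def write_manifest(outdir: Path, spec: CohortSpec, extra: Mapping[str, Any] | None = None) -> None:
    """Write the run manifest: config, its hash, seed and library versions."""
    config = _config_dict(spec)
    canonical = json.dumps(config, sort_keys=True)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": spec.seed,
        "versions": {
            "drltiming": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_CSV_FLOAT_FORMAT = "%.6f"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def run_pipeline(
    spec: CohortSpec,
    outdir: str | Path,
    fit_weeks: Sequence[int] | None = None,
    fit_mode: FitMode | str = FitMode.MLE,
    effect_week: int = 11,
    simulate_pr: bool = True,
    overwrite: bool = False,
) -> dict[str, Path]:
    """simulate -> analyze -> fit -> report, writing all tables to ``outdir``.

    The report step runs a two-group t-test of week-``effect_week`` mean
    efficiency (CIE vs CON) and converts it to Cohen's d and r; when
    ``simulate_pr`` is on, each subject also runs one progressive-ratio
    session with its week-``effect_week`` parameters and the groups' pooled
    press times are compared with the exact KS statistic.

    Outputs are deterministic functions of the spec: rerunning with an
    identical spec yields byte-identical files.
    """
    from scipy import stats as sps

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if (outdir / "manifest.json").exists() and not overwrite:
        raise InvalidInputError(
            f"{outdir} already holds a pipeline run; pass overwrite=True to replace it"
        )

    sessions = simulate_cohort(spec)
    paths = {"events": outdir / "events.csv"}
    write_event_log(sessions, paths["events"])

    metrics = session_metrics_table(sessions)
    weekly = weekly_summary_table(sessions)
    binned = binned_irt_table(sessions)
    fit_weeks = tuple(fit_weeks) if fit_weeks is not None else (effect_week,)
    fits = fit_table(sessions, mode=fit_mode, weeks=fit_weeks, seed=spec.seed)
    for name, df in [
        ("session_metrics", metrics),
        ("weekly_summary", weekly),
        ("binned_irt", binned),
        ("fit_params", fits),
    ]:
        paths[name] = outdir / f"{name}.csv"
        _write_csv(df, paths[name])

    # -- report: effect sizes + KS on PR pressing ---------------------------
    effect_rows = []
    wk = weekly[weekly["week"] == effect_week].dropna(subset=["mean_efficiency"])
    for measure, table, col in [
        ("efficiency", wk, "mean_efficiency"),
        ("burst_decay_L", fits[fits["week"] == effect_week], "L"),
    ]:
        cie = table[table["group"] == Group.CIE.value][col].to_numpy()
        con = table[table["group"] == Group.CON.value][col].to_numpy()
        if cie.size >= 2 and con.size >= 2:
            t_stat = float(sps.ttest_ind(cie, con).statistic)
            es = effect_size_from_t(t_stat, cie.size, con.size)
            effect_rows.append(
                {
                    "measure": measure,
                    "week": effect_week,
                    "mean_cie": float(np.mean(cie)),
                    "mean_con": float(np.mean(con)),
                    "t": es.t_value,
                    "df": es.df,
                    "cohen_d": es.d,
                    "r": es.r,
                }
            )
    paths["effect_sizes"] = outdir / "effect_sizes.csv"
    _write_csv(pd.DataFrame(effect_rows), paths["effect_sizes"])

    if simulate_pr:
        pr_cfg = ScheduleConfig(kind=ScheduleKind.PR)
        press_by_group: dict[str, list[np.ndarray]] = {"CIE": [], "CON": []}
        pr_rows = []
        for g_idx, group in enumerate((Group.CON, Group.CIE)):
            for s_idx in range(spec.n_per_group):
                rng = np.random.default_rng([spec.seed, 1000 + g_idx, s_idx])
                params = spec.baseline_params
                if group is Group.CIE and effect_week in spec.cie_effects:
                    params = spec.cie_effects[effect_week].apply(params)
                presses, result = simulate_pr_session(params, pr_cfg, rng)
                kept = presses[presses <= result.termination_time_s]
                press_by_group[group.value].append(kept)
                pr_rows.append(
                    {
                        "subject_id": f"{group.value}{s_idx + 1:02d}",
                        "group": group.value,
                        "reinforcers_earned": result.reinforcers_earned,
                        "breakpoint_ratio": result.breakpoint_ratio,
                        "total_responses": result.total_responses,
                        "termination_time_s": result.termination_time_s,
                    }
                )
        paths["pr_results"] = outdir / "pr_results.csv"
        _write_csv(pd.DataFrame(pr_rows), paths["pr_results"])
        pooled_cie = np.concatenate(press_by_group["CIE"] or [np.zeros(0)])
        pooled_con = np.concatenate(press_by_group["CON"] or [np.zeros(0)])
        ks_rows = []
        if pooled_cie.size and pooled_con.size:
            d_stat = ks_two_sample(pooled_cie, pooled_con)
            ks_rows.append(
                {
                    "comparison": "pr_press_times_CIE_vs_CON",
                    "D": d_stat,
                    "n_cie": pooled_cie.size,
                    "n_con": pooled_con.size,
                }
            )
        paths["ks_pr"] = outdir / "ks_pr.csv"
        _write_csv(pd.DataFrame(ks_rows), paths["ks_pr"])

    write_manifest(outdir, spec)
    paths["manifest"] = outdir / "manifest.json"
    return paths
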