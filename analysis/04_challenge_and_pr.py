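#!/usr/bin/env python
"""DRL20 challenge contrast, week-11 effect sizes, and progressive ratio.

Three analyses on top of the simulated cohort:

1. Challenge: each subject's week-10 DRL15 average vs a one-session DRL20
   switch (higher criterion = higher cognitive load -> efficiency drops).
2. Effect sizes: week-11 CIE-vs-CON t-tests on mean efficiency and on the
   fitted burst decay L, converted to Cohen's d and r.
3. Progressive ratio: one PR session per subject at week-11 parameters;
   group cumulative pressing compared with the exact two-sample KS D.

Outputs under results/cohort/: challenge.csv, effect_sizes.csv,
pr_results.csv, ks_pr.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from drltiming import (
    Day,
    Group,
    ScheduleConfig,
    ScheduleKind,
    challenge_comparison,
    drl,
    effect_size_from_t,
    ks_two_sample,
    read_event_log,
    simulate_pr_session,
)
from drltiming.io import _write_csv, fit_table, weekly_summary_table
from drltiming.synthetic import DEFAULT_BASELINE_PARAMS, DEFAULT_CIE_EFFECTS

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20180626
CHALLENGE_WEEK = 10


def main() -> None:
    events = OUTDIR / "events.csv"
    if not events.exists():
        raise SystemExit(f"{events} not found - run analysis/01_simulate_cohort.py first")
    sessions = read_event_log(events)

    # 1. DRL20 challenge vs the week-10 DRL15 average, per subject
    rows = []
    by_subject: dict[str, list] = {}
    for s in sessions:
        if s.week_index == CHALLENGE_WEEK:
            by_subject.setdefault(s.subject_id, []).append(s)
    for subj_idx, (subj, week_sessions) in enumerate(sorted(by_subject.items())):
        rng = np.random.default_rng([SEED, 7, subj_idx])
        group = week_sessions[0].group
        params = DEFAULT_BASELINE_PARAMS
        if group is Group.CIE and CHALLENGE_WEEK in DEFAULT_CIE_EFFECTS:
            params = DEFAULT_CIE_EFFECTS[CHALLENGE_WEEK].apply(params)
        from drltiming import simulate_session

        challenge = simulate_session(
            params, drl(20.0), rng, subject_id=subj, group=group,
            day=Day.WED, week_index=CHALLENGE_WEEK,
        )
        rec = challenge_comparison(week_sessions, challenge)
        rows.append(
            {
                "subject_id": subj,
                "group": group.value,
                "drl15_mean_efficiency": rec.drl15_mean_efficiency,
                "drl20_efficiency": rec.challenge_efficiency,
                "efficiency_change": rec.efficiency_change,
            }
        )
    challenge_df = pd.DataFrame(rows)
    _write_csv(challenge_df, OUTDIR / "challenge.csv")
    print(
        "mean efficiency change under DRL20 challenge: "
        f"{challenge_df['efficiency_change'].mean():+.1f} points"
    )

    # 2. week-11 effect sizes on efficiency and fitted L
    weekly = weekly_summary_table(sessions)
    wk11 = weekly[weekly["week"] == 11].dropna(subset=["mean_efficiency"])
    fits = fit_table(sessions, weeks=(11,), seed=SEED)
    effect_rows = []
    for measure, table, col in [
        ("efficiency", wk11, "mean_efficiency"),
        ("burst_decay_L", fits, "L"),
    ]:
        cie = table[table["group"] == "CIE"][col].to_numpy()
        con = table[table["group"] == "CON"][col].to_numpy()
        t_stat = float(sps.ttest_ind(cie, con).statistic)
        es = effect_size_from_t(t_stat, cie.size, con.size)
        effect_rows.append(
            {"measure": measure, "t": es.t_value, "df": es.df,
             "cohen_d": es.d, "r": es.r,
             "mean_cie": cie.mean(), "mean_con": con.mean()}
        )
        print(
            f"week-11 {measure}: CIE {cie.mean():.2f} vs CON {con.mean():.2f}, "
            f"t({es.df}) = {es.t_value:.2f}, d = {es.d:.2f}, r = {es.r:.2f}"
        )
    _write_csv(pd.DataFrame(effect_rows), OUTDIR / "effect_sizes.csv")

    # 3. progressive ratio at week-11 parameters
    pr_cfg = ScheduleConfig(kind=ScheduleKind.PR)
    press_pool = {"CIE": [], "CON": []}
    pr_rows = []
    for g_idx, group in enumerate((Group.CON, Group.CIE)):
        params = DEFAULT_BASELINE_PARAMS
        if group is Group.CIE:
            params = DEFAULT_CIE_EFFECTS[11].apply(params)
        for s_idx in range(8):
            rng = np.random.default_rng([SEED, 8, g_idx, s_idx])
            presses, result = simulate_pr_session(params, pr_cfg, rng)
            press_pool[group.value].append(
                presses[presses <= result.termination_time_s]
            )
            pr_rows.append(
                {"subject_id": f"{group.value}{s_idx + 1:02d}", "group": group.value,
                 "reinforcers_earned": result.reinforcers_earned,
                 "breakpoint_ratio": result.breakpoint_ratio,
                 "total_responses": result.total_responses}
            )
    pr_df = pd.DataFrame(pr_rows)
    _write_csv(pr_df, OUTDIR / "pr_results.csv")
    d_stat = ks_two_sample(
        np.concatenate(press_pool["CIE"]), np.concatenate(press_pool["CON"])
    )
    _write_csv(
        pd.DataFrame(
            [{"comparison": "pr_press_times_CIE_vs_CON", "D": d_stat}]
        ),
        OUTDIR / "ks_pr.csv",
    )
    print(
        "PR: mean breakpoint ratio "
        + ", ".join(
            f"{g} {pr_df[pr_df['group'] == g]['breakpoint_ratio'].mean():.1f}"
            for g in ("CON", "CIE")
        )
        + f"; KS D on pooled press times = {d_stat:.3f}"
    )


if __name__ == "__main__":
    main()
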