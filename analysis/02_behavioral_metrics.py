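#!/usr/bin/env python
"""Descriptive behavior: efficiency, stability, weekly averages, IRT bins.

Reads the simulated event log, computes per-session metrics, checks the
training stability rule (<10% variation in efficiency over 3 consecutive
sessions), averages Tue-Thu sessions into weekly summaries, and writes the
pooled 0.5-s binned IRT distributions.

Outputs under results/cohort/: session_metrics.csv, weekly_summary.csv,
binned_irt.csv.
"""

from pathlib import Path

import pandas as pd

from drltiming import read_event_log, stability_check
from drltiming.io import (
    _write_csv,
    binned_irt_table,
    session_metrics_table,
    weekly_summary_table,
)

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    events = OUTDIR / "events.csv"
    if not events.exists():
        raise SystemExit(f"{events} not found - run analysis/01_simulate_cohort.py first")
    sessions = read_event_log(events)

    metrics = session_metrics_table(sessions)
    weekly = weekly_summary_table(sessions)
    binned = binned_irt_table(sessions)
    _write_csv(metrics, OUTDIR / "session_metrics.csv")
    _write_csv(weekly, OUTDIR / "weekly_summary.csv")
    _write_csv(binned, OUTDIR / "binned_irt.csv")

    # stability over each subject's prevapor week (the training criterion)
    stable = {
        subj: stability_check(
            g.sort_values("day")["efficiency"].to_numpy()
        )
        for subj, g in metrics[metrics["week"] == 0].groupby("subject_id")
    }
    n_stable = sum(bool(v) for v in stable.values())
    print(f"{n_stable}/{len(stable)} subjects stable in the prevapor week")

    pivot = weekly.pivot_table(
        index="week", columns="group", values="mean_efficiency"
    ).round(1)
    print("weekly mean efficiency (%):")
    print(pivot.to_string())
    print(f"wrote tables to {OUTDIR}")


if __name__ == "__main__":
    main()
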