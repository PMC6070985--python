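#!/usr/bin/env python
"""Simulate the full synthetic cohort and write its event log.

Design: n = 8 rats per group (CIE vs CON), DRL15 30-min sessions, 5 days a
week over the 12-week timeline — prevapor (week 0), vapor exposure (weeks
1-6), forced abstinence (weeks 7-11).  CIE subjects carry the late-abstinence
phenotype in weeks 9-11: burst decay rate L halved and the timed mean shifted
right by 5%.

Output: results/cohort/events.csv (+ manifest).  Downstream drivers read it.
"""

from pathlib import Path

from drltiming import CohortSpec, simulate_cohort, write_event_log
from drltiming.io import write_manifest

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20180626


def main() -> None:
    spec = CohortSpec(seed=SEED)
    sessions = simulate_cohort(spec)
    OUTDIR.mkdir(parents=True, exist_ok=True)
    write_event_log(sessions, OUTDIR / "events.csv")
    write_manifest(OUTDIR, spec)
    n_resp = sum(s.n_responses for s in sessions)
    print(f"simulated {len(sessions)} sessions, {n_resp} responses")
    print(f"wrote {OUTDIR / 'events.csv'}")


if __name__ == "__main__":
    main()
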