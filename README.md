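# drltiming

Analysis pipeline for operant response-timing experiments under
**differential reinforcement of low rates (DRL)** schedules — the standard
rodent assay of response inhibition (inverse impulsivity). It targets the
within-subjects chronic-intermittent-ethanol (CIE) design: rats are trained
to DRL15 (only responses whose inter-response time exceeds 15 s are
reinforced), then followed through vapor exposure and forced abstinence,
with a one-session DRL20 cognitive-load challenge and a progressive-ratio
(PR) motivation probe.

The package provides, as importable library code plus numbered analysis
drivers:

* **Schedule engines** — deterministic scorers for DRL-N, the adjusting DRL
  used to shape from 2 s to 15 s (criterion × 1.0075 after every reinforced
  response, carried over between sessions), and PR with the 15-min
  breakpoint rule.
* **A synthetic cohort generator** — sessions are renewal processes of IRTs
  drawn from the temporal-regulation mixture below, assembled into a
  two-group (CIE vs control), 12-week, 5-sessions-per-week design with
  week-scheduled group effects, so the whole pipeline is testable without
  animal data.
* **The temporal-regulation (TR) mixture model** of the IRT distribution,

  $$f(t) = p\,\Gamma(t-\delta;N,c) + q(1-p)\,L e^{-L(t-\delta)} + (1-q)(1-p)\,L' e^{-L'(t-\delta)},$$

  fitted per subject by maximum likelihood (or least squares on the
  cumulative frequency distribution), with the derived response-inhibition
  measures: response threshold θ = N·c/15, Weber fraction ω = 1/√N, and the
  component proportions (timed *p*, burst *q(1−p)*, long *(1−q)(1−p)*).
* **Descriptive statistics** — efficiency of reinforcement
  (100 × reinforcers/responses), 0.5-s × 120-bin IRT distributions,
  Tuesday–Thursday weekly averaging, the <10%-variation stability rule, and
  the DRL15-vs-DRL20 challenge contrast.
* **Effect sizes and group comparisons** — Cohen's *d* from a t statistic
  (d = t·√(1/n₁+1/n₂)), r = d/√(d²+4), an exact two-sample
  Kolmogorov–Smirnov D (sup over pooled points, with an optional seeded
  permutation p-value), and blood-ethanol-concentration utilities
  (noise-floor correction, 125–250 mg/dL target-range check).

## Worked example

```python
import numpy as np
import drltiming as dt

params = dt.TRParams(p=0.7, q=0.6, N=6.0, c=2.67, L=2.0, Lprime=0.05, delta=0.3)
irts = dt.sample_irts(params, np.random.default_rng(0), 2000)
fit = dt.fit_tr_model(irts, seed=1)
```

prints (via the snippet in `analysis/`-style reporting):

```
p-hat      = 0.713   (timed proportion; truth 0.700)
L-hat      = 2.164   (burst decay rate, 1/s; truth 2.000)
theta      = 1.076   (timed mean / 15 s criterion)
omega      = 0.419   (Weber fraction, 1/sqrt(N))
burst prop = 0.181   (q(1-p); truth 0.180)
effect size: t(12) = 2.27, d = 1.213, r = 0.52
DRL15 demo: flags=[True, True, False], efficiency=66.7%
```

The fit recovers the generating parameters of 2000 simulated IRTs: ~71% of
responses are timed (gamma component peaking just above the 15-s criterion,
θ ≈ 1.08, i.e. accurate timing), ~18% are short bursts decaying at ≈2/s, and
the rest are long task-delinquent pauses. The effect-size line converts a
two-group t statistic with n = 7 per group into d and r; the DRL15 demo
scores responses at 16 s, 40 s and 45 s (IRTs 16, 24, 5 s → two of three
reinforced).

## Analysis drivers

Run from the repository root; each writes tables under `results/cohort/`:

```sh
python analysis/01_simulate_cohort.py    # events.csv: 960 sessions, n=8/group
python analysis/02_behavioral_metrics.py # efficiency, stability, weekly means, IRT bins
python analysis/03_fit_tr_model.py       # per-subject TR fits, weeks 0 and 11
python analysis/04_challenge_and_pr.py   # DRL20 challenge, effect sizes, PR + KS
```

The same stages are available as a CLI (`drltiming simulate|fit|analyze|
report|fixtures`) driven by a YAML cohort config.

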