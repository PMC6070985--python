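# Methods

## The behavioral model

Under a DRL-N schedule only responses whose inter-response time (IRT)
strictly exceeds the criterion are reinforced, so an efficient subject must
withhold responding for N seconds. The package models the marginal IRT
distribution as a shifted three-component mixture (the temporal-regulation,
TR, model):

* a **gamma component** (weight *p*, shape *N*, scale *c*) for timed
  responses governed by an internal interval estimate centred at *N·c*;
* a **fast exponential** (weight *q(1−p)*, rate *L*) for short response
  bursts — failures of inhibition;
* a **slow exponential** (weight *(1−q)(1−p)*, rate *L′*) for very long,
  task-delinquent pauses.

All components are shifted by *δ*, the smallest elicitable IRT (a motor
floor). Derived measures: response threshold θ = N·c/criterion (θ < 1 means
the timed peak sits below the criterion — premature timing), Weber fraction
ω = 1/√N (the coefficient of variation of the gamma component, the standard
scalar-timing precision index; the TR literature offers no other closed
form, so the package commits to this one), and the component proportions.

Sessions are modeled as renewal processes: IRTs i.i.d. within a session, no
post-reinforcement pause term, no within-session drift. This is the weakest
point of the generative model (real rats pause after consuming a reinforcer
and drift across a 30-min session), but it matches the model's own
assumption that the marginal IRT distribution is the unit of analysis.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| p | timed proportion | 0.70 | inside the empirically typical 0.6–0.8 band |
| q | burst share of non-timed | 0.60 | gives burst ≈ 0.18, long ≈ 0.12 |
| N | gamma shape | 6.0 | ω ≈ 0.41, realistic timing precision |
| c | gamma scale (s) | 2.67 | N·c = 16.0 s → θ ≈ 1.07 (slightly conservative timing) |
| L | burst decay (1/s) | 2.0 | mean burst IRT 0.5 s |
| L′ | long-pause decay (1/s) | 0.05 | mean pause 20 s |
| δ | shift (s) | 0.3 | plausible motor floor |

The derived proportions (timed 0.70, burst 0.18, long 0.12) and threshold
bracket the values typically reported for trained rats. The cohort design
defaults to n = 8 per group, 12 weeks (prevapor week 0, vapor weeks 1–6,
abstinence weeks 7–11), 5 sessions/week of 30 min.

The synthetic CIE phenotype is injected in weeks 9–11 as L × 0.5 (burst
responding decays half as fast — i.e. the model's signature of the
late-abstinence reduction in short bursts) and c × 1.05 (a 5% rightward
shift of the timed mean). These multipliers are fixture choices encoding the
direction and a plausible magnitude of the group effect, not empirical
claims; the pipeline's job is to recover their direction from raw simulated
event logs. Optional per-subject log-normal scatter on (N·c, L) is off by
default so parameter-recovery checks measure estimator error, not designed
heterogeneity.

## Schedule engines

* DRL scoring uses strict inequality (IRT > criterion) and measures the
  first response's IRT from session start — the "timer since last event"
  convention of operant chambers; this also makes the empty-history case
  well defined. Reinforcer delivery does not reset a separate timer.
* Adjusting DRL multiplies the criterion by 1.0075 after each reinforced
  response, saturating exactly at the 15-s target; the closed form
  ⌈log(target/start)/log(1.0075)⌉ is guarded by direct iteration against
  floating-point edge effects (from 2 s, the target is first reached on
  reinforced response #270).
* Progressive ratio: the progression list is explicit configuration (the
  progression used in any given lab is not standardised); the packaged
  default [1, 2, 4, 6, 9, 12, 15, 20, 25, 32, 40, 50] is a test scaffold.
  The 15-min hang limit is checked between consecutive presses and from
  session start to the first press; presses after the breakpoint gap are
  discarded and the session terminates at last press + hang limit.

## Fitting

Maximum likelihood is the default objective; a CDF least-squares mode
(squared deviations between empirical and model CDF at the 120 half-second
bin edges) reproduces spreadsheet-style fits applied to the cumulative
frequency distribution. Numerical choices:

* δ is fixed at min(IRT) − 1 ms per subject rather than estimated jointly —
  a free shift touching the smallest observation creates a likelihood
  singularity.
* Optimisation is unconstrained in (logit p, logit q, log N, log c, log L,
  log L′) via L-BFGS-B, 500 iterations max, ftol 1e-10 / gtol 1e-6.
* Starting values are stratified moments: p₀ from the fraction of IRTs in
  (0.5·criterion, 2·criterion), gamma moments from that stratum, L₀ and L′₀
  from the mean IRT below 2 s and above 2·criterion, with generic fallbacks
  for empty strata. Five jittered restarts (σ = 0.3 on the internal scale,
  seeded, deterministic) guard against local minima; the best objective
  wins.
* Densities are floored at 1e-12 inside the log-likelihood so observations
  at/below δ (possible after 1-ms rounding) cannot produce −∞.
* N is a positive real (gamma family, not Erlang). No L′ < L constraint is
  imposed; on realistic data the components separate on their own.
* Non-convergence is reported as `converged=False` with the optimizer
  message, never as an exception; fits on fewer than 30 IRTs warn.
* The mixture log-density is evaluated directly from gammaln/xlogy rather
  than through distribution objects: per-call overhead dominated cohort-scale
  fitting otherwise. scipy.stats serves as the independent oracle in tests.

## Descriptive statistics

* Efficiency = 100 × reinforcers/responses per session; a zero-response
  session has *undefined* efficiency and propagates as missing (logged),
  never as silent zero.
* IRT histograms use half-open [k·0.5, (k+1)·0.5) bins, 120 bins to 60 s;
  longer IRTs go to an explicit overflow counter and percentages are
  relative to the total including overflow, so the 120 bins sum to ≤ 100.
* Weekly summaries average Tuesday–Thursday sessions only (Mondays follow
  the weekend break, Fridays follow blood-draw stress); a week with no
  usable included day yields NaN.
* The stability rule "<10% variation in efficiency over 3 consecutive
  sessions" is interpreted as (max − min)/mean < 0.10 within a sliding
  window — no formula is standard, and range-over-mean is the strictest
  common reading. Fewer sessions than the window returns "not assessable"
  (None), not False.

## Effect sizes and comparisons

Cohen's d from an independent-samples t uses d = t·√(1/n₁+1/n₂), and
r = d/√(d²+4); this chain is exact arithmetic on the printed t and group
sizes. The two-sample KS statistic is computed exactly as the supremum of
|ECDF difference| over the pooled sample points — appropriate for the small
group sizes of PR cumulative curves — with an optional seeded permutation
p-value instead of the asymptotic one. BEC readings subtract the 3.9 mg/dL
instrument noise floor (clamped at zero) before the inclusive 125–250 mg/dL
target-range check; the mg/dL→mM helper uses the standard 46.07 g/mol
molecular weight and is a convenience, not a validated output.

## What the generator does and does not show

Passing tests establish that the pipeline recovers what was injected into
data generated under the model's own assumptions: schedule scoring is exact,
the MLE recovers (p, L, N·c) at n = 2000 IRTs within a few percent, a halved
burst-decay rate in the CIE group is detected directionally in ≥80% of
replicate cohorts, and the DRL20 challenge mechanically lowers efficiency
for θ ≈ 1.07 responders (their timed peak clears 15 s but not 20 s). They do
not establish robustness to model misspecification — post-reinforcement
pauses, within-session drift, between-session learning, or PR-specific
motivational dynamics (synthetic PR pressing differs between groups only
through the IRT mixture, so group PR curves nearly coincide; real motivation
differences produce much larger KS separations). Problem sizes in the test
and acceptance runs (20 fit replicates at 2000 IRTs, 50 replicate one-week
cohorts, 100 challenge subjects) were chosen as the smallest designs at
which the checked contrasts are stable.

## Known limitations

* Per-rat fitting only; no hierarchical pooling across subjects.
* The event-log CSV carries no schedule metadata; the reader attaches it
  from configuration (default DRL15).
* Adjusting-DRL shaping is simulated and scored but the cohort generator
  starts cohorts already at DRL15, as the design assumes trained subjects.
* Repeated-measures ANOVA with post hoc correction is out of scope; the
  pipeline exports tidy tables for external statistics software.
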