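# Methods

## Scoring models

The ILD-GAP index assigns integer points to Gender, Age and Physiology for
a patient with interstitial lung disease:

| Variable | Bin | Points |
|---|---|---|
| Diagnosis | IPF or unclassifiable ILD | 0 |
| | CVD-IP, iNSIP, CHP | −2 |
| Sex | female / male | 0 / 1 |
| Age (y) | ≤60 / 61–65 / >65 | 0 / 1 / 2 |
| %FVC | >75 / 50–75 / <50 | 0 / 1 / 2 |
| %DLco | >55 / 36–55 / ≤35 / cannot perform | 0 / 1 / 2 / 3 |
| %Monocytes (ILD-GAPM only) | ≤8.5 / >8.5 | 0 / 1 |

ILD-GAPM adds the monocyte point to the ILD-GAP total. Both totals map to
stages with the same cut-offs: stage I (≤1), II (2–3), III (4–5), IV (>5).
Negative totals (possible for the adjusted diagnoses) are stage I.

**Bin boundaries for real-valued inputs.** The printed bins are
integer-styled. To partition the reals exhaustively and disjointly we use
age ≤60 / (60,65] / >65, %FVC >75 / [50,75] / <50 and %DLco >55 / (35,55]
/ ≤35. Integer inputs reproduce the printed table exactly. The DLco middle
bin is left-open at 35 (rather than closed at 36) so that values such as
35.5 have a home, consistent with the "≤35" lower bin.

**Monocyte cut.** 8.5% is a fixed model constant (the development
cohort's median), not recomputed per cohort; a `monocyte_cut="median"`
plan option re-derives it from the cohort at hand for sensitivity
analyses. A DLco flagged *unmeasurable* scores the 3-point bin; a silently
missing DLco is a schema error — the 3-point bin encodes clinical
inability to perform the test, not missing data.

**HRCT global score.** Each lung is divided into three zones; each of the
six zones carries a semiquantitative extent grade 0–4 per abnormality
(ground-glass opacity, honeycombing). The global score is the sum over
zones (0–24), per abnormality. The percent-extent→grade mapping is not
standardised; the default dialect uses quartile bins (0, (0,25], (25,50],
(50,75], (75,100]) and the interior edges are configurable.

## Synthetic cohort generator

The generator emulates a single-centre ILD cohort: n = 179 by default,
subtype mix 56/112/6/5 (IPF / CVD-IP+iNSIP / CHP / UC-ILD) with
subtype-specific male fractions (0.88, 0.57, 0.67, 1.00), and truncated
normal covariates — age 73 ± 9 y (≥18), %FVC 94.2 ± 18.8, %DLco
92.9 ± 30.5, monocyte ratio 8.6 ± 2.8% (all > 0). Truncation resamples
rather than clips, keeping densities smooth. The combined CVD-IP/iNSIP
mass is split evenly between the two labels; the scores treat them
identically. Monocyte counts are derived as ratio × a truncated-normal
leukocyte count (6700 ± 1500 /µL), giving counts near 575 ± 225 /µL.
HRCT scores and the comorbidity index are rounded clipped draws chosen to
match the reference marginals (honeycomb 1.8 ± 2.7 in IPF vs 0.2 ± 0.8
otherwise; GGO 4.7 ± 2.9; CCIS ~ Poisson(1)); they carry no built-in
hazard and exist so the univariate screen has realistic columns.

**Event model.** Event times follow a proportional-hazards law whose
linear predictor is β × (ILD-GAPM total), β = ln 1.35 per point by
default — the score is the true model, which makes parameter-recovery and
discrimination checks well posed. The default time law is exponential
(constant baseline hazard), chosen over Weibull because it admits
closed-form calibration; a Weibull shape parameter is accepted for
robustness experiments. An optional `lp_noise_sd` adds independent
Gaussian noise to the linear predictor to degrade discrimination toward
realistic clinical levels.

**Censoring and calibration.** Follow-up is min(event time, exponential
dropout, 1095 days administrative censoring). The baseline hazard is
calibrated by bisection so the expected observed-event fraction at three
years equals the 12% target, using the exact per-subject probability
λ/(λ+r_c)·(1−e^{−(λ+r_c)τ}) under the exponential law (log-spaced-grid
quadrature under Weibull) over a 50,000-subject score sample drawn with a
fixed internal seed — the calibrated rate is therefore a deterministic
function of the population parameters, independent of the cohort seed.
The default dropout rate 7.6 × 10⁻⁴/day was chosen analytically so the
mean observed follow-up is ≈679 days once the event hazard is accounted
for. A single seed drives independent sub-streams for covariates, event
times and censoring via a spawned seed sequence.

**What the generator does not emulate:** correlations between physiology
and monocytes beyond those induced by the score, time-varying monocyte
trajectories, HRCT–outcome coupling, competing risks and informative
censoring. Passing tests therefore demonstrate correctness of the
estimators and the direction of the model comparison under a
proportional-hazards world, not clinical performance on real cohorts.

## Survival estimators

All estimators are implemented here directly; lifelines, scikit-survival
and scikit-learn appear only as independent cross-checks in the tests.

* **Kaplan–Meier**: product-limit over distinct event times; tied events
  decrement simultaneously; a subject censored at an event time stays in
  that event's risk set (censoring after event at ties).
* **Log-rank**: k-group observed-minus-expected with hypergeometric
  covariance; statistic from the first k−1 groups via a linear solve;
  χ² upper tail on k−1 df. Undefined (error) with no events.
* **Harrell's C**: a pair is comparable when the shorter follow-up is an
  event (at tied times, when exactly one is an event, taken to fail
  first); tied predictions count ½. Exact O(n²) evaluation.
* **Time-dependent AUC**: cumulative/dynamic definition at a fixed
  horizon (default 1095 days = 3 × 365) with inverse-probability-of-
  censoring weights from the Kaplan–Meier censoring-survival estimate G:
  cases (events by τ) weighted 1/G(T−), controls weighted 1/G(τ−).
  Controls are subjects event-free *through* the horizon — including
  those administratively censored exactly at it, which matters when the
  study design truncates follow-up at the horizon itself. The estimator
  agrees exactly with Uno-style implementations on data extending past
  the horizon, and reduces to the binary Mann–Whitney AUC of 1{T≤τ} when
  no one is censored before τ. A guard rejects weights where G = 0;
  given the left-limit construction this cannot trigger while cases and
  controls both exist, but it protects degenerate resamples.
* **Cox (univariate)**: Newton–Raphson with step halving on the partial
  likelihood of a single standardised covariate, Efron tie correction by
  default (better with heavily tied integer scores; Breslow available
  for oracle comparison). SE from observed information; 95% CI
  exp(β̂ ± 1.96 SE); AIC = −2 logPL(β̂) + 2. Monotone likelihood (event
  order separated by the predictor) raises a convergence error rather
  than returning a divergent estimate.
* **Bootstrap**: subject resampling with replacement, B = 2000 by
  default, normal-approximation CI (estimate ± 1.96 × bootstrap SE).
  Resamples where a statistic is undefined are dropped and counted. With
  a fixed seed the index matrix depends only on (seed, B, n), so two
  predictors evaluated on one cohort share identical resamples — the
  ILD-GAP vs ILD-GAPM comparison is paired by construction.

## Pipeline choices

* The univariate screen fits each candidate predictor separately in the
  IPF and non-IPF strata, flags P < 0.05 two-sided, unadjusted — a
  deliberate reproduction of descriptive clinical screening; no
  multiple-testing correction is applied.
* The low-diffusing-capacity subgroup uses a fixed ≤90% predicted
  threshold (exposed in the plan) rather than a per-cohort median, so
  analyses stay comparable across cohorts.
* Monocyte ratio is preferred over monocyte count throughout; a
  count-based screen mode exists.
* Model AIC/discrimination use the integer total score as a single Cox
  covariate by default; a "stage" mode uses the ordinal stage number
  (1–4) as the single covariate. A categorical-stage fit would need a
  multivariable Cox model, which is out of scope here.
* Strata or populations with fewer than two non-empty groups, zero
  events, or constant predictors are skipped with a logged warning;
  an error is raised only when nothing at all is analysable. All row
  exclusions (e.g. zero follow-up) are logged.
* Report artefacts are a deterministic function of (cohort, plan):
  re-running regenerates every file bit-identically.

## Problem sizes used in the test suite

Marginal-convergence checks run at n = 100,000 (tolerance 3 Monte-Carlo
SEs); the event-fraction calibration check at n = 50,000 (±0.5 percentage
points); Cox coverage of the generating log-HR at 100 replicates ×
n = 2,000 (≥90/100 CIs must cover); the direction-only model comparison
at the study scale n = 179 across 50–60 replicates (majority wins
required per metric). These sizes make each check's Monte-Carlo error
comfortably smaller than its tolerance.

## Known limitations

* Proportional hazards and exponential (or Weibull) baselines are
  assumptions of the generator, not validated properties of ILD cohorts.
* The C-index bootstrap is O(B·n²); adequate at clinical cohort sizes,
  slow beyond n ≈ 5,000.
* The stage-mode AIC treats stage as ordinal, not categorical.
* No competing-risks machinery; the composite endpoint (ILD-related death
  or first acute exacerbation within three years) sidesteps it by design.
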