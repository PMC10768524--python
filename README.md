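# ildgapm

Prognostic scoring and survival evaluation for interstitial lung disease
(ILD) cohorts: the **ILD-GAP** composite index (Gender, Age, Physiology,
with a −2 adjustment for CVD-IP/iNSIP/CHP) and its extension **ILD-GAPM**,
which adds one point when the blood monocyte ratio exceeds 8.5% of
leukocytes. The package is aimed at clinical researchers who want to
score cohorts, compare the two models' ability to predict 3-year
ILD-related events (ILD-related death or first acute exacerbation), and
stress-test the whole evaluation pipeline on synthetic cohorts when
patient data cannot be shared.

## The models

For a patient with diagnosis d, sex s, age a, %FVC f, %DLco g and
monocyte ratio m:

```
ILD-GAP  = P_dx(d) + P_sex(s) + P_age(a) + P_FVC(f) + P_DLco(g)       ∈ [−2, 8]
ILD-GAPM = ILD-GAP + 1{m > 8.5%}                                      ∈ [−2, 9]
```

with P_dx ∈ {0, −2}, P_sex ∈ {0,1}, P_age ∈ {0,1,2}, P_FVC ∈ {0,1,2},
P_DLco ∈ {0,1,2,3} ("cannot perform" = 3). Totals map to stages
I (≤1), II (2–3), III (4–5), IV (>5). See `docs/methods.md` for the full
point table and bin-boundary conventions.

The evaluation stack — Kaplan–Meier, k-group log-rank, Harrell's C,
IPCW time-dependent AUC at a 3-year horizon, univariate Cox fits
(Efron ties) with AIC, and paired bootstrap CIs — is implemented from
scratch and cross-checked in the tests against lifelines,
scikit-survival and scikit-learn.

## Worked example

Simulate a study-sized cohort (n = 179, ~12% 3-year event rate, hazard
ratio 1.35 per score point) and run the full analysis:

```sh
ildgapm simulate --seed 17 --out cohort.csv
ildgapm report --in cohort.csv --seed 17 --outdir results/
```

which prints

```
simulated 179 subjects (seed 17) -> cohort.csv
model comparison (n=179, events=13): AUC 0.762 vs 0.768, C 0.728 vs 0.732,
AIC 118.5 vs 118.0 (ILD-GAP vs ILD-GAPM)
artefacts -> results/
```

Reading: on this cohort ILD-GAPM discriminates 3-year events slightly
better than ILD-GAP (higher time-dependent AUC and concordance) and fits
better (lower AIC) — the expected direction, since the simulated hazard
acts through the full ILD-GAPM score including the monocyte point. With
only 13 events the margins are small; across replicates ILD-GAPM wins
the majority on all three metrics (this is asserted by the test suite).
`results/` contains the scored cohort, the univariate Cox screen split by
IPF / non-IPF, Kaplan–Meier curve tables with log-rank P values per
stratifier (monocyte group, honeycombing, model stage) and population
(all, IPF, non-IPF, %DLco ≤ 90), the paired model comparison with
bootstrap CIs, and a run log. Everything regenerates bit-identically
from (cohort file, plan, seed).

The same steps from Python:

```python
from ildgapm import SimulationConfig, generate_cohort, AnalysisPlan, compare_models

cohort = generate_cohort(SimulationConfig(seed=17))
cm = compare_models(cohort, AnalysisPlan(seed=17))
print(cm.ild_gapm.auc, cm.ild_gapm.auc_ci, cm.winners)
```

Single patients score through `PatientRecord` / `score_record`; cohort
CSVs through `read_cohort` / `score_cohort` or `ildgapm score`.

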