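# osteofrailia

Quantitative toolkit for sex-specific low bone-mineral-density (BMD)
thresholds on the DXA T-score scale: T-score/Z-score arithmetic against
reference databases, Gaussian population-prevalence modelling of BMD
cutpoints, study-level pooling of fracture T-scores, subject-level
threshold sensitivity analysis of prospective cohorts, and a seeded
fracture-cohort simulator with an analytic (exponential-tilting) oracle.

## The problem

Densitometric osteoporosis is defined for older women as a femoral-neck
(FN) T-score ≤ −2.5, where

```
T = (BMD_patient − BMD_young-adult mean) / SD_young-adult
```

against a sex-specific young-adult reference database.  Older men,
however, suffer hip fragility fractures at FN T-scores roughly 0.5–0.6
*higher* than older women — largely because older male T-score
distributions sit higher (US community means: −1.241 for men vs −1.717
for women; difference 0.476).  Applying the female cutpoint −2.5 to men
therefore captures a far smaller slice of the male population (≈10.7% vs
≈23.3%) and misses most male fractures.  This package implements the
machinery for deriving and evaluating a male-specific low-BMD category
("osteofrailia", FN T ≤ −2.0 for Caucasian men, ≤ −2.1 for Chinese men):

* **Gaussian prevalence**: `P(T ≤ c) = Φ((c − μ)/σ)` per population,
  with older-population T-score SDs obtained as the older/young BMD-SD
  ratio (e.g. 0.139/0.137 for US men), and its inverse for
  prevalence-matched cutpoints;
* **sex offsets**: equal-weight pooled male-minus-female fracture
  T-score differences, and risk-equivalent cutpoints `c_M = c_F + Δ`;
* **cohort sensitivity**: fraction of prospective fracture cases with
  baseline T ≤ c versus the fraction of the whole cohort labelled;
* **simulation**: per-sex Gaussian T-score populations with a
  complementary-log-log gradient-of-risk model
  `risk(T) = 1 − exp(−h·e^{−βT})`, whose fracture-case mean has the
  closed rare-event limit `μ − β·σ²` (exponential tilting) — so equal
  risk gradients plus shifted population means reproduce, by
  construction, the parallelism between case and population sex
  differences.

## Worked example

```python
from osteofrailia import (
    default_registry, prevalence_below, prevalence_matched_cutpoint,
    hk_fixture_cohorts, sensitivity_at_threshold, cohort_prevalence,
)

reg = default_registry()
men, women = reg.population("us_older_m"), reg.population("us_older_f")

print(f"{100 * prevalence_below(-2.5, women):.1f}")   # 23.3  (% of older women at T <= -2.5)
print(f"{100 * prevalence_below(-2.5, men):.1f}")     # 10.7  (% of older men at the same cutpoint)
print(f"{100 * prevalence_below(-2.0, men):.1f}")     # 22.7  (% of older men at T <= -2.0)
print(f"{prevalence_matched_cutpoint(-2.5, women, men, ratio=1.0):.2f}")  # -1.98

cohort = hk_fixture_cohorts()["M"]        # 2000 men, 63 hip fractures over follow-up
print(str(sensitivity_at_threshold(cohort, -2.7)))    # 15.9% (10/63)
print(str(sensitivity_at_threshold(cohort, -2.1)))    # 46.0% (29/63)
print(str(cohort_prevalence(cohort, -2.1)))           # 15.5% (310/2000)
```

A female cutpoint of −2.5 and a male cutpoint of −2.0 define
prevalence-comparable categories (23.3% vs 22.7%), and in the Hong Kong
prospective cohorts the analogous male threshold raise (−2.7 → −2.1)
lifts the fraction of male hip-fracture cases flagged at baseline from
15.9% to 46.0%, on par with the 44.9% flagged in women by their own
threshold.

The narrative analyses live under `analysis/` (each writes its table to
`results/`):

1. `01_population_prevalence.py` — Gaussian prevalences and
   prevalence-matched male cutpoints;
2. `02_sex_offsets.py` — pooled fracture and community sex offsets,
   risk-equivalent cutpoints;
3. `03_cohort_sensitivity.py` — threshold sensitivity in the
   marginal-constrained Hong Kong cohort fixtures;
4. `04_threshold_report.py` — the composite per-ethnicity threshold
   report;
5. `05_simulation_parallelism.py` — the simulator vs the tilt oracle and
   the case/population parallelism.

A thin CLI mirrors the library (`osteofrailia --help`): `tscore`,
`prevalence`, `cutpoint`, `pool`, `sex-offset`, `cohort-sens`,
`cohort-prev`, `cohort-stats`, `derive-report`, `simulate`,
`make-fixture`.

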