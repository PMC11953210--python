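# Methods

## Scales and conventions

All analyses run on the DXA T-score scale.  A T-score is defined against
a *reference database* — the young-adult mean and SD of areal BMD
(g/cm²) for one (site, sex, ethnicity, device) combination — as
`T = (BMD − young_mean) / young_SD`.  Because this map is affine, any
population that is Gaussian in BMD is Gaussian in T, with

* `mean_t = (mean_bmd − young_mean) / young_SD`,
* `sd_t = sd_bmd / young_SD` — i.e. the older-population T-score SD is
  the older/young BMD-SD ratio.  This ratio definition is the unique
  choice consistent with the linear map; it is how the shipped
  population models obtain their T-score SDs (US men: 0.139/0.137 ≈
  1.015; US women: 0.129/0.120 = 1.075; Hong Kong men 0.115/0.130,
  women 0.107/0.100).

Threshold comparisons are closed (`T ≤ c`) everywhere; ties count as
below.  All values are carried at full floating precision; rounding —
one decimal, half away from zero — happens only at report boundaries
(this display convention reproduces e.g. 15.9 from 10/63 and 46.0 from
29/63).  Ethnicity and device are opaque labels, not enums: which
reference database a clinic uses is itself a contested choice, and the
registry must not pretend to more harmonization than exists.

## Population prevalence model

The fraction of an older population at or below a cutpoint is the
Gaussian closed form `Φ((c − mean_t)/sd_t)`; its inverse gives the
cutpoint for a target prevalence, and composing the two gives
prevalence-matched cutpoints across populations (optionally scaled by an
incidence ratio, e.g. 0.5 for the roughly 2:1 female:male hip-fracture
incidence).  Gaussianity is a modelling assumption: the reference
surveys publish means and SDs, not percentiles, so no heavier-tailed
alternative is identifiable from the available inputs.  Against the
published population percentages (10.8 / 23.4 / 22.7), the model built
from the rounded means (−1.241, −1.717) and SD ratios agrees to within
±0.2 percentage points, which is the documented tolerance; the residual
0.05–0.1-point gaps are consistent with rounding of the published
parameters themselves.

The classical anchor — a female cutpoint 2.5 SD below the young mean
producing a prevalence equal to the female lifetime hip-fracture risk
(≈16%) — is illustrated by `cutpoint_for_prevalence` in the docs but not
asserted numerically: that 1994 calibration used a different reference
distribution than the survey parameters shipped here.

## Study pooling and sex offsets

Published fracture series report group mean T-scores; the pooled mean
gives each study equal weight (no sample-size weighting), matching how
such cross-study comparisons are summarized; `by_n` weighting is
available but not the default.  The sex offset is the male-minus-female
difference of pooled means, with mixed-sex series excluded (their sex
composition is unknown).  No random-effects meta-analysis or
heterogeneity statistics are attempted: the inputs are a handful of
group means without consistent variance reporting.

The shipped study tables are of two kinds.  `studies_printed.csv`
carries group summaries published as numbers (the Hong Kong prospective
fracture groups −1.97 ± 0.72 men / −2.59 ± 1.00 women, the Australian
series, the US and Hong Kong community means).  The per-study dots
behind the pooled European offset of 0.59 were published only
graphically, so `studies_fig1_synthetic.csv` is a clearly-labelled
*synthetic* study set constructed to carry the published pooled
aggregates (female pooled −2.91, male pooled −2.32, offset 0.59, with
mixed-sex means between the two); no test asserts its per-study values,
only the aggregates it encodes.

## Threshold derivation

Risk-equivalent male cutpoints are the female cutpoint plus the fracture
sex offset: −2.5 + 0.59 = −1.91 (reported as −1.9, adopted as −2.0 for
convenience) for Caucasian men.  The Chinese male threshold −2.1 is a
*configured constant* adopted from the revised Chinese
reference-threshold literature; the offset arithmetic −2.7 + 0.62 =
−2.08 is documented as consistent with it, but the package does not
claim it as the derivation.  Likewise the standalone total-hip threshold
−1.7 and the lumbar-spine "working" threshold −2.0 are configured
constants flagged with a status field (`adopted` / `working`), because
no formula for them exists; the FN→TH linear mapping machinery
(`fit_site_mapping`, ordinary least squares plus Pearson correlation) is
provided for users with paired data, the published anchors
(−2.5 → −2.13 at r = 0.801; −2.5 → −2.38 at r = 0.840) being
correspondences without published regression coefficients.

## Cohort analysis

Sensitivity at a threshold is the fraction of fracture cases with
baseline T ≤ c; cohort prevalence is the same fraction over all
subjects; both are cells/margins of the 2×2 classification table, whose
counts must reconcile exactly (integer conservation is tested).  Crude
fractions only — no time-to-event modelling, competing risks, or age
standardization — because the quantities of interest are the published
crude capture fractions with fixed denominators (63, 69, 2000).
Subjects with missing baselines are rejected at load rather than
dropped, precisely to keep denominators fixed.

## Synthetic cohorts and the tilting oracle

`fixture_cohort_from_marginals` rebuilds a subject-level cohort from
published marginals: total n, case count, exact counts below stated
thresholds (per stratum), and optional group mean/SD targets.  Values
are placed at equally spaced quantiles of a Normal(μ, σ) truncated to
each between-threshold bin — strictly interior, so every count is exact
by construction — with (μ, σ) either solved so the stratum's sample
moments hit the targets (tolerance 0.02 on the mean, 0.05 on the SD;
a least-squares solve, typically exact to machine precision) or, absent
targets, fitted to the bin fractions on the probit scale.  The
construction is fully deterministic: identical marginals yield an
identical table, so fixtures are stable across versions.  The shipped
Hong Kong fixtures (2000 men with 63 cases, 2000 women with 69)
reproduce every published count exactly and the fracture-group moments
to the placement tolerance; subject-level values are synthetic — only
the marginals were published — so any statistic of these fixtures other
than the encoded marginals (e.g. non-case group moments) is an artifact
of the placement and carries no evidential weight about the real
cohorts.

The cohort simulator draws per-sex baseline T-scores from
Normal(mean_t, sd_t) and fracture indicators independently with
probability `risk(T) = 1 − exp(−h·e^{−βT})`, `h = −ln(1 −
baseline_risk)`.  The complementary-log-log form (rather than logistic)
is deliberate: under it the case distribution is exactly the population
Gaussian reweighted by `e^{−βT}` in the rare-event limit, i.e. shifted
to `mean_t − β·sd_t²` with unchanged SD (exponential tilting).  Hence
two sexes with equal β and σ show case-mean differences equal to their
population-mean differences — the formal statement of the observed
parallelism between fracture-case and community sex differences — and
the exact case mean `E[T·risk(T)]/E[risk(T)]`, evaluated by adaptive
quadrature over μ ± 15σ, serves as an analytic oracle for the simulator.
The risk model deliberately encodes only the population-mean-shift
mechanism; other contributors to the male–female difference (e.g. trauma
energy) are outside the model, so simulator output demonstrates
sufficiency of the mean-shift mechanism, not exclusivity.

Parameter defaults and their rationale:

* **β = 0.7 per T-score unit** in the demo analyses (relative risk ≈ 2.0
  per SD): chosen to reproduce the observed tilt magnitude — e.g. the
  female community mean −1.76 vs the female fracture-case baseline mean
  −2.59 implies a shift of ≈0.8 ≈ β·σ² with σ ≈ 1.  A package choice, not
  a published gradient.
* **Baseline risks** are calibrated, not set: `calibrate_baseline_risk`
  root-finds the baseline so the population incidence `E[risk(T)]` hits
  a target to 1e-6 (monotone in the baseline, solved by Brent's method).
  Demo targets: the Hong Kong case counts (63/2000 men, 69/2000 women
  over ~9-10 years) or a 1%/2% male/female pair encoding the ≈2:1
  female:male incidence ratio.
* **Rare-event accuracy**: the tilt formula is an asymptotic limit; at
  baseline risk 0.005 in the low-T population regimes used here the
  exact case mean agrees with `μ − β·σ²` to within 1% of the case mean.
  At higher baseline risks (saturating hazard) the case mean is pulled
  slightly toward the population mean and the between-sex parallelism
  acquires a small analytic gap (≈0.01 T-units at baseline risk 0.02),
  which is why the parallelism demonstrations run in the rare-event
  regime — matching the actual rarity of hip fracture over follow-up.
* **PRNG**: one generator family (numpy's default PCG64), seed always
  explicit in the spec; identical spec + seed gives bit-identical
  output.

## Problem sizes and numerical choices

Monte-Carlo agreement checks use 10⁶ draws (closed form vs empirical
fraction within 3 standard errors); simulator-vs-oracle checks use 10⁶
subjects (≈3–15k cases depending on incidence), sizes at which the
3-standard-error bands are a few hundredths of a T-score unit and the
whole suite runs in seconds.  Quadratures carry absolute tolerance 1e-9
/ relative 1e-6 with explicit convergence checks; the prevalence/
cutpoint inversion round-trips to 1e-9 and T-score/BMD arithmetic to
1e-12 over the physical domain.  Degenerate inputs (zero variance pairs,
empty selections, single-subject groups) raise typed errors or flagged
NaNs rather than silent values.

## Known limitations

* The Gaussian population model inherits the rounding of its published
  parameters; prevalences are meaningful to ~0.1–0.2 percentage points.
* Quantile mapping between reference populations does not reproduce
  cross-ethnicity threshold equivalences published via other routes
  (e.g. the Chinese −2.1 ↔ Caucasian −2.0 correspondence), which is why
  such thresholds ship as configured constants.
* The cohort fixtures are marginal reconstructions, not the real
  subject-level data; conclusions from them are exactly as strong as
  the published marginals they encode, no stronger.
* The simulator has no age structure, time-varying hazards, bone-loss
  trajectories, or trauma-energy covariates; it exists to make the
  population-mean-shift mechanism quantitative, not to forecast absolute
  risk.
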