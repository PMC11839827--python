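# Methods

## Scope and perspective

`hrucost` implements an incidence-based, bottom-up cost-of-illness analysis
for the 3-month follow-up after acute low-risk pulmonary embolism (PE),
from a societal perspective: direct medical costs (anticoagulation,
ambulatory visits, rehospitalisation, non-anticoagulant medications,
follow-up diagnostics, sundry medical items, formal/informal help including
rehabilitation) plus indirect costs from productivity loss. Costs accrue
from the index event forward; with a 3-month horizon no discounting is
applied. Intangible losses are not valued. The reference population is the
German subcohort (n = 326, 21 centres) of a prospective early-discharge
management study; all unit costs are German 2021 €.

## Costing rules

Every countable resource on the questionnaire carries a disease-attribution
sub-count (or flag) recorded by the site investigator; component costs are
`count × unit cost` for the total and `PE sub-count × unit cost` for the
excess part, so `0 ≤ attributable ≤ total` holds per component by
construction. Specific conventions:

- **Anticoagulation** (drug-days × per-day price) is always fully
  PE-attributable: it is index-event therapy.
- **Ambulatory visits** are priced per specialty. The statutory-insurance
  fee schedule is configuration, not a constant; the shipped two-tier
  default (general practitioner 63.49 €, specialist 193.09 €) is calibrated
  jointly with the generator's visit mix so the implied mean fee is
  ≈ 115.33 €/visit overall and ≈ 76.45 €/visit for PE-related visits —
  the ratios of the published cohort-mean visit costs to the published
  visit counts (1873.04/16.24 and 194.95/2.55). The GP shares themselves
  (overall 0.6; PE-related 0.9) are a modelling choice made once for
  plausible fee magnitudes; two equations then determine the two fees.
- **Rehospitalisation** uses an opaque per-inpatient-day price (658.27 €);
  diagnosis-related-group case mix was not recorded and is out of scope.
- **Other medications** (non-anticoagulant) have no published unit prices
  and are carried as self-reported euro amounts (pass-through), with a
  self-reported PE-attributed part.
- **Formal/informal help** is priced per visit (15 €) from the visit count;
  the questionnaire's "period of help, days" is kept as a descriptive field
  only. Rehabilitation days (inpatient or outpatient) are priced per clinic
  day (135.25 €).
- **Productivity loss** (human-capital method): the categorical absence
  answer is imputed as 0 / 21 / 63 days (none / ≤ 6 weeks → 3 weeks /
  > 6 weeks → 9 weeks), at 7 calendar days per week. The 7-day convention
  is deliberate: it is the only encoding under which the published mean
  absence of 33.05 days over 115 absent patients is reproduced by an
  integer split of patients (82 × 21 + 33 × 63 = 3801 = 115 × 33.052); the
  343.95 €/day price is correspondingly read as labour cost per calendar
  day of absence. Costs accrue only to patients employed before the event —
  `unknown` employment (49/326) cannot be affirmed employed and contributes
  zero — and the whole absence is valued (no friction-period cap).
  Productivity loss after the acute event is treated as entirely
  disease-specific, so indirect attributable = indirect total.

Prices live in a registry (`table1_2021_de.yaml`) at full floating
precision; looking up an unregistered item is an error, never a silent
zero. Inflation (CPI) and purchasing-power-parity adjustments compose as
multiplicative factors from user-supplied series; the package ships only
the identity series, since index values are data, not code.

## Missing data

A missing answer in a cost category is interpreted as *no utilisation* and
replaced with zero, provided the patient answered at least one cost
question; a patient who answered none is excluded from the cohort
denominator entirely. The policy is idempotent and total; exclusions are
reported, not silently dropped. Demographics (age, sex, BMI, creatinine
clearance, employment status) are required for subgroup classification;
rows lacking them are rejected with a per-row validation report.

## Aggregation and uncertainty

Cohort component means are over all included patients (zeros in the
denominator). Excess-cost fractions are ratios of cohort means — sum of
attributable component means over sum of total component means — never
means of patient-level ratios; only the ratio-of-means definition is
consistent with the published percentages (e.g. 862.64/3019.33 → 28.6%).

95% CIs for component means use an intercept-only gamma GLM with log link,
fitted by IRLS (statsmodels): the score equation of the log-link intercept
model makes the fitted mean exactly the arithmetic mean, and a Wald
interval on the intercept is exponentiated. Dispersion is Pearson
χ²/(n − 1); intervals are Wald, not profile (standard GLM practice; the
choice matters little at n = 326). The gamma model has no mass at zero, so
components with any zero-cost patient are routed to a seeded percentile
bootstrap of the mean (default 2000 resamples); an opt-in ε-shift
(add 0.01 €, fit, subtract) exists for comparability. A constant cost
vector (e.g. anticoagulation, 279 € for every patient) has zero dispersion
and degenerates to a point interval. Percentile bootstrap intervals on
heavily zero-inflated, skewed components sit slightly below nominal
coverage (≈ 93–94% at n = 326 in our simulations); this is a known property
of the percentile method and is documented rather than corrected.

Subgroups (age ≤ 65 vs > 65; women vs men; any of active cancer, COPD,
chronic heart failure, coronary artery disease, diabetes vs none; fragile —
age > 75 **or** creatinine clearance < 50 ml/min **or** BMI < 18.5 kg/m²,
all strict — vs non-fragile) are total classifiers: strata partition the
cohort and the size-weighted stratum means decompose the cohort mean
exactly. Stratified reports show direct costs by default, with a switch to
include the indirect component. Empty strata are flagged `undefined`
rather than propagating NaNs. Money is rendered to 2 decimals and
percentages to 1 decimal, half-up, only at the report layer.

## Synthetic cohort generator

The study's patient-level data are not deposited, so the generator emulates
the published *marginals* of the 326-patient cohort; its defaults are the
study conditions, not tuning knobs:

- **Demographics**: truncated normals (age mean 55.1, SD 16.7, range 19–86;
  BMI 28.0 ± 5.9 above 13; creatinine clearance 80.5 ± 18.8 above 10) whose
  location parameter is solved (Brent) so the *post-truncation* mean equals
  the published mean — using the published mean directly as the location
  would bias age by ≈ 0.6 years. Sex: P(female) = 0.467. Employment:
  yes/no/unknown = 157/120/49 of 326.
- **Comorbidities**: five Bernoulli marginals (16, 19, 6, 23, 24 of 326)
  coupled by a single shared Gaussian-copula factor with ρ = 0.3026, solved
  by Gauss–Hermite quadrature so that P(any comorbidity) = 68/326 holds
  jointly with the marginals (independence would give 0.243 instead of
  0.209).
- **Ambulatory visits**: 96% of patients visit; conditional counts are
  1 + negative binomial (dispersion knob, default size 1.2) with the
  unconditional mean fixed at 16.24. PE-related visits are a *structural
  subset*: among PE-visitors (207/313 of visitors), one index visit plus
  binomial thinning of the remainder, giving an exact unconditional mean of
  2.55 and `pe ≤ total` always. Visits split GP/specialist with the mixes
  noted above.
- **Rehospitalisation**: P = 29/326, one stay, length of stay log-normal
  moment-matched to 11.65 ± 22.02 days and rounded to whole days (min 1;
  discretisation bias < 0.01 day); 10/29 of stays PE-related. The published
  text elsewhere reports 35 hospitalised patients; 29 is used because only
  29 × 11.65 × 658.27/326 ≈ 682 € reproduces the published per-patient
  rehospitalisation cost (682.51 €) — a documented inconsistency in the
  source tables.
- **Rehabilitation/help/diagnostics/items**: Bernoulli onset probabilities
  and moment-matched count laws per the published utilisation table;
  echocardiography and compression ultrasound are Bernoulli {0,1} (their
  per-patient multiplicity is not published); PE sub-counts by binomial
  thinning at the published PE-to-total mean ratios. Non-anticoagulant
  medication spending is log-normal conditional on use (P = 0.35, a free
  choice; only the unconditional mean 19.06 € and SD 50.10 € are published
  and both are matched).
- **Absence**: P(absent | employed) = 115/157; P(≤ 6 weeks | absent) =
  82/115 — the derived integer split above. With the 21/63-day imputation
  this fixes the expected indirect cost at 4010.29 €/patient exactly.

Generation is a pure function of (config, seed). `calibration_report`
draws replicate cohorts and z-scores every targeted marginal against its
published value (|z| < 3 is the pass criterion); conditional means over
random denominators (length of stay among the ~29 hospitalised, absence
days among the absent) use pooled cluster ratio estimators across
replicates, whose Monte-Carlo standard errors are far better behaved than
per-replicate means of heavy-tailed quantities. Calibration targets are
always the published values, not the active config, so a deliberately
off-target config is flagged rather than self-justified.

What the generator does *not* emulate: joint structure beyond the published
marginals and conditionals (e.g. the true correlation between visit counts
and hospitalisation), within-patient longitudinal detail, or multi-stay
readmission patterns. Passing calibration therefore shows the pipeline is
correct under study-like marginals — it does not validate inferences that
depend on unpublished joint structure (notably the subgroup cost *levels*,
which the source study derived from real patient-level data).

## Problem sizes and determinism

Simulation-based checks use study-sized cohorts (n = 326): 200 replicate
cohorts for generator calibration, 1000 gamma-GLM and 2000 bootstrap
coverage replicates (1000 resamples per interval in the coverage runs;
the analysis default remains 2000). All stochastic paths take explicit
seeds; identical configuration yields byte-identical report artifacts,
bootstrap CIs included.

## Known limitations

- Ambulatory fee levels are inferred, not published; only the implied mean
  fees are anchored. Analyses sensitive to the GP/specialist split should
  supply their own fee schedule.
- The per-day hospital price embeds an unknown case mix; payer-perspective
  (reimbursement) costing is out of scope.
- Employment `unknown` is conservatively costed at zero productivity loss,
  which understates indirect costs if some of those 49 patients were
  employed.
- The percentile bootstrap's mild undercoverage on zero-heavy components
  (above) and the categorical absence imputation (21/63 days) are inherent
  approximations of the data actually collected.
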