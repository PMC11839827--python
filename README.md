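# hrucost

Bottom-up cost-of-illness analysis of healthcare resource utilisation (HRU)
questionnaires collected during the 3-month follow-up of acute **low-risk
pulmonary embolism (PE)**, from a societal perspective.

The package is for health economists and clinical researchers who need to
turn patient-level questionnaire answers — drug-days, physician visits,
readmissions, diagnostics, rehabilitation, help at home, work absence — into
per-patient and cohort-level euro figures with uncertainty, and to quantify
which part of those costs is attributable to the index PE event ("excess
costs"). Because the underlying study's patient-level data are not publicly
deposited, the package also ships a seedable synthetic cohort generator
calibrated to the published marginals of the 326-patient German subcohort,
so the full pipeline is runnable and testable out of the box.

## The model

For patient $i$ and cost component $k$ (anticoagulation, ambulatory visits,
rehospitalisation, other medications, diagnostics, other medical expenses,
formal/informal help incl. rehabilitation, productivity loss), bottom-up,
incidence-based costing multiplies resource counts $x_{ik}$ by standardised
German unit costs $c_k$ (2021 €):

$$C_{ik} = x_{ik}\,c_k, \qquad C_{ik}^{PE} = x_{ik}^{PE}\,c_k,$$

where $x^{PE}_{ik} \le x_{ik}$ is the sub-count the site investigator
attributed to the PE. Indirect costs use the **human-capital method**: the
questionnaire's categorical absence answer (none / ≤ 6 weeks / > 6 weeks) is
imputed as 0 / 21 / 63 days, each day valued at 343.95 €, counted only for
patients employed before the event, and fully PE-attributable. No
discounting is applied over the 3-month horizon.

Cohort means keep zeros in the denominator, and every excess-cost fraction
is a **ratio of mean costs** (mean attributable ÷ mean total), not a mean of
patient-level ratios. 95% CIs come from an intercept-only **gamma GLM with
log link** (whose fitted mean equals the arithmetic mean) for strictly
positive components, and from a seeded percentile bootstrap for zero-heavy
ones. Missing cost answers count as zero utilisation provided the patient
answered at least one cost question; patients who answered none are excluded
from the denominator.

## Worked example

```bash
python examples/cohort_report.py
```

simulates a calibrated 326-patient cohort (seed 1), costs it, and prints:

```
n = 326 patients, 3-month horizon, 2021 EUR

Costs related to anticoagulation at follow-up          279.00 [  279.00,   279.00]  PE   279.00
Costs related to ambulatory visits                    1824.31 [ 1633.18,  2016.50]  PE   169.54
Costs related to rehospitalisation                     585.58 [  276.58,   985.44]  PE   135.29
...
Costs related to productivity loss                    4586.35 [ 3788.73,  5362.38]  PE  4586.35

Direct costs                                          2951.46
Indirect costs (productivity loss)                    4586.35
Overall costs                                         7537.81

PE-attributable share of overall costs : 70.1%
```

Each row is a cohort mean with its 95% CI and the PE-attributable part.
Anticoagulation is 90 days × 3.10 € for everyone (CI collapses to the
point); productivity loss dominates overall costs; a single simulated cohort
scatters stochastically around the published aggregates (overall ≈ 7030 €,
≈ 69% PE-attributable). `examples/cost_single_patient.py` shows one
patient's breakdown, `examples/subgroup_analysis.py` the stratified direct
costs (age, sex, comorbidity, fragility), and
`examples/calibration_check.py` the generator-vs-targets z-score table.

There is also a thin CLI:

```bash
hrucost simulate --n 326 --seed 1 --out cohort.csv
hrucost validate cohort.csv
hrucost report --cohort cohort.csv --out-dir out/ --seed 1
```

which writes `per_patient_costs.csv`, `table3_utilisation.csv`,
`table4_components.csv`, `fractions.json` and `subgroups.csv`, each with a
JSON provenance sidecar (config hash, seed, version).

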