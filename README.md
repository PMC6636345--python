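# cohortwatch

An active drug-surveillance pipeline for EMR-style tables: new-user cohort
identification with a full attrition tree, incident-outcome subcohorts,
analysis-ready covariate mapping, propensity-score matching with balance
diagnostics, intention-to-treat / as-treated follow-up construction, and
survival analysis (incidence densities with exact CIs, Kaplan-Meier, Cox
proportional hazards). A synthetic EMR generator with known ground truth
(confounded treatment assignment, proportional-hazards outcomes, stochastic
refill gaps) makes the whole system testable without real clinical data.

## Inputs

Three CSVs (schema fixed by column name):

- `patients.csv`: `patient_id,birth_date,sex,data_end_date`
- `diagnoses.csv`: `patient_id,date,code,setting` (setting ∈ outpatient,
  inpatient, emergency)
- `prescriptions.csv`: `patient_id,drug_code,start_date,days_supplied`

plus a YAML study config declaring the study window, exposure/outcome code
sets (exact or prefix matching), inclusion/exclusion criteria, covariate
templates, and analysis options (washout 365 d, lookback 365 d, follow-up
cap 730 d, refill grace gap 30 d, caliper 0.2 on the logit-SD scale, SMD
threshold 0.1, α = 0.05 by default).

## CLI

```bash
cohortwatch validate --config study.yml
cohortwatch run      --config study.yml --inputs data/ --out results/ [--seed N]
cohortwatch simulate --spec sim.yml --config study.yml --out results/
```

`run` writes, per outcome: the attrition table/tree, analysis-ready
dataset, matched pairs, before/after SMD balance table, ITT+AT follow-up
records, incidence summaries, KM curve data, and Cox hazard ratios — plus
`manifest.json` (config hash, seed, row counts, output hash) and `run.log`.
Identical config + seed + inputs reproduce the result CSVs byte-for-byte.
`simulate` generates synthetic tables from a simulation spec, runs the
study on them, and writes `recovery.json` comparing estimated hazard
ratios and post-match balance against the generator's latent truth.

Exit codes: 0 ok, 2 config error, 3 data validation error, 4 statistical
failure.

## Notes on methods

- Refill-gap rule: a *greater than* 30-day gap between supply end and next
  start discontinues an episode (a gap of exactly 30 days does not); AT
  follow-up censors at the first episode's last supply end.
- Incidence density is reported per 100,000 person-days; cumulative
  incidence CIs use the exact Poisson (Garwood) interval by default, with
  Clopper-Pearson available via `ci_method: clopper_pearson`.
- Propensity scores come from an in-package IRLS logistic regression;
  matching is greedy 1:1 nearest-neighbor without replacement in a
  seed-derived order, caliper 0.2 × SD of the logit score by default.
- Cox fits maximize the partial likelihood by Newton-Raphson (Efron tie
  correction by default, Breslow available); fits with any coefficient
  se > 2 are flagged unstable but still reported; monotone likelihoods
  raise an explicit error.

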