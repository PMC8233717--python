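# efimm

Electronic frailty-index measurement and outcome analysis for claims/EHR
cohorts of older adults newly treated for multiple myeloma (MM).

## The problem

Direct frailty assessment does not scale to large retrospective cohorts, but
an *electronic* frailty index can be computed from routinely collected
administrative claims and electronic-health-record codes.  `efimm`
implements a 31-item deficit-accumulation index of the VA-FI-10 family: for
each patient the index is

```
F = d / D,      d = number of catalog deficits with >= 1 qualifying code
                    in the lookback window,  D = 31
```

with qualifying codes drawn from a configurable deficit -> ICD/procedure
code catalog, a lookback window of (index − 3 years, index] ending at
treatment initiation, and deficits seen in either payer source (internal
"VA" records or external "CMS" claims) counted once.  Severity categories
use the validated cut-points: non-frail F ≤ 0.1, pre-frail 0.1 < F ≤ 0.2,
mildly frail 0.2 < F ≤ 0.3, moderately frail 0.3 < F ≤ 0.4, severely frail
F > 0.4.

Around the index the package provides the full study pipeline:

* **cohort construction** — ≥3 MM diagnosis dates (ICD-9 `203.0*` /
  ICD-10 `C90.0*`), index date at the first treatment code with a second
  within 183 days, index year 2004–2017, age ≥ 65, VA utilization in each of
  the 3 pre-index years, CMS-treatment washout — with a per-step attrition
  table;
* **baseline covariates** — ISS stage from albumin/β2-microglobulin,
  lab-abnormality flags (Ca ≥ 11 mg/dL, Cr > 2 mg/dL, Hgb < 10 g/dL,
  Plt < 150×10³/µL), demographics, and induction-therapy classification
  (novel = proteasome inhibitor or immunomodulatory agent in the 90 days
  after index);
* **outcomes** — overall survival and time to first unplanned VA
  hospitalization (death treated as censoring), administratively censored
  2019-06-30; Kaplan–Meier curves with medians and CIs, log-rank tests,
  uni-/multivariable Cox models (h(t|x) = h₀(t)·exp(xᵀβ)), chained-equations
  multiple imputation with Rubin's-rules pooling, complete-case and
  2012–2017 sensitivity reruns;
* **measurement-variant analysis** — paired comparison of VA-only vs
  VA+CMS sources and 1- vs 3-year windows: mean intra-individual change
  with paired t-test, % reclassified to a higher severity category,
  % changing by ≥ 0.1, and HR-stability tables;
* **a synthetic-EHR generator** — latent-frailty single-factor model with
  calibrated deficit prevalences, payer splitting, Weibull
  proportional-hazards outcomes and full ground-truth recording, so the
  whole pipeline is testable without restricted clinical data.

## Worked example

```bash
python examples/04_survival_analysis.py
```

simulates 1500 patients whose death hazard rises with true severity,
scores them, and fits the survival models:

```
Kaplan-Meier by severity (median survival, years):
  non-frail          n=   67  median=       5.68  S(1y)=0.836
  pre-frail          n=  326  median=       4.30  S(1y)=0.850
  mildly frail       n=  531  median=       2.93  S(1y)=0.795
  moderately frail   n=  346  median=       2.57  S(1y)=0.783
  severely frail     n=  228  median=       1.48  S(1y)=0.610

log-rank: chi2=109.7, df=4, p=8.51e-23

unadjusted Cox hazard ratios vs non-frail:
  fi_pre_frail   HR=1.20 (95% CI 0.86-1.70)
  fi_mild        HR=1.62 (95% CI 1.16-2.25)
  fi_moderate    HR=1.94 (95% CI 1.38-2.72)
  fi_severe      HR=2.99 (95% CI 2.11-4.24)
```

Median survival shortens and the hazard ratio rises monotonically across
severity — the dose–response pattern the generator planted, recovered by
the measurement and modeling stages.  `examples/05_variant_reclassification.py`
shows the measurement-variation analysis (mean paired change +0.044 when the
external payer is added, 38.6% of patients reclassified upward), and the
other examples cover simulation, attrition and variant scoring.

A thin CLI wraps the same stages:

```bash
efimm run --n 1000 --seed 42 --out out/        # end-to-end, all artifacts
efimm simulate --n 500 --seed 7 --out data/    # synthetic bundle + truth
efimm validate data/                           # schema + integrity report
efimm cohort data/ --out out/                  # decisions + attrition
efimm score data/ --window-years 3 --sources VA,CMS --out scores.csv
efimm compare-variants data/ --baseline va_only,3y --comparator va_cms,3y --out cmp.csv
```

`efimm run` writes `table1.csv` (characteristics by severity), `table2.csv`
(deficit prevalence by severity), `table3.csv` (unadjusted/adjusted HRs),
`attrition.csv`, KM curve data, the variant comparison, and a
`manifest.json` with config hash, seed and stage timings; reruns with the
same seed are byte-identical.

## Data formats

Bundles are three UTF-8 CSVs with ISO-8601 dates — `patients.csv`
(patient_id, birth_date, sex, race, income, last_activity_date,
death_date), `events.csv` (patient_id, event_date, code, code_system ∈
ICD9/ICD10/PROC/RX, source ∈ VA/CMS, care_setting, admission_type) and
`labs.csv` (patient_id, date, analyte, value).  The shipped deficit catalog
uses a synthetic demo code vocabulary; production users load their own
validated code lists via `efimm.load_catalog` (CSV: deficit_id, name,
domain, code_system, match_rule, pattern).

See `docs/methods.md` for the measurement conventions, generator model and
numerical choices.
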