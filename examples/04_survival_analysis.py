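"""Kaplan-Meier and Cox analysis of death by frailty severity.

Simulates a cohort whose death hazard rises with true severity (log-HR
ladder 0/0.285/0.565/0.854/1.135 vs non-frail), scores patients, builds
survival records censored administratively at 2019-06-30, and fits both the
product-limit curves and an unadjusted Cox model with category contrasts.
"""

from efimm import (
    MeasurementConfig,
    OutcomeType,
    SimulationConfig,
    build_cohort,
    build_survival_records,
    cox_fit,
    default_catalog,
    km_estimate,
    logrank,
    score_patient,
    simulate_cohort,
)
from efimm.survival import encode_design, records_frame

bundle, truth = simulate_cohort(SimulationConfig(n_patients=1500, seed=29))
decisions, _ = build_cohort(bundle)
catalog = default_catalog()
events_by = bundle.events_by_patient()
scores = {
    d.patient_id: score_patient(
        events_by[d.patient_id], catalog, MeasurementConfig(), d.index_date, patient_id=d.patient_id
    )
    for d in decisions
    if d.included
}
records = build_survival_records(bundle, decisions, OutcomeType.DEATH, scores)

print("Kaplan-Meier by severity (median survival, years):")
for label, curve in km_estimate(records).items():
    med = f"{curve.median:.2f}" if curve.median is not None else "not reached"
    s1 = curve.horizons[1.0][0]
    print(f"  {label:18s} n={curve.n:5d}  median={med:>11s}  S(1y)={s1:.3f}")

chi2, df, p = logrank(records)
print(f"\nlog-rank: chi2={chi2:.1f}, df={df}, p={p:.2e}")

frame = records_frame(records)
design = encode_design(frame, ["category"])
design[["time", "event"]] = frame[["time", "event"]]
fit = cox_fit(design, [c for c in design.columns if c not in ("time", "event")])
print("\nunadjusted Cox hazard ratios vs non-frail:")
for cov, row in fit.table.iterrows():
    print(f"  {cov:14s} HR={row['hr']:.2f} (95% CI {row['ci_lower']:.2f}-{row['ci_upper']:.2f})")
print("\nA monotone HR ladder reproduces the dose-response pattern the")
print("hazard model planted; medians shorten with increasing severity.")
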