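"""Measurement-variant reclassification: VA-only vs VA+CMS scoring.

For each included patient the index is measured twice from the same event
stream — once ignoring the CMS payer, once with both sources — and the
paired differences are summarized: mean intra-individual change with a
paired t-test, the share reclassified to a higher severity category, and
the share whose score rises by >= 0.1.
"""

from efimm import (
    MeasurementConfig,
    SimulationConfig,
    Source,
    build_cohort,
    compare_fi_variants,
    default_catalog,
    score_patient,
    simulate_cohort,
)

bundle, _ = simulate_cohort(SimulationConfig(n_patients=800, seed=37, source_split=0.25))
decisions, _ = build_cohort(bundle)
catalog = default_catalog()
events_by = bundle.events_by_patient()

va = MeasurementConfig(window_years=3, sources=frozenset({Source.VA}), label="va_only,3y")
both = MeasurementConfig(window_years=3, label="va_cms,3y")

scores_va, scores_both = {}, {}
for d in decisions:
    if not d.included:
        continue
    evs = events_by[d.patient_id]
    scores_va[d.patient_id] = score_patient(evs, catalog, va, d.index_date, patient_id=d.patient_id)
    scores_both[d.patient_id] = score_patient(evs, catalog, both, d.index_date, patient_id=d.patient_id)

comp = compare_fi_variants(scores_va, scores_both, label_a="va_only,3y", label_b="va_cms,3y")

print(f"patients compared:              {comp.n}")
print(f"mean intra-individual change:   {comp.mean_delta:+.3f} "
      f"(95% CI {comp.ci[0]:+.3f} to {comp.ci[1]:+.3f})")
print(f"paired t-test p-value:          {comp.p_value:.2e}")
print(f"reclassified to higher category: {comp.pct_reclassified_up:.1f}%")
print(f"score increase >= 0.1:           {comp.pct_delta_ge_threshold:.1f}%")
print()
print("Adding the external payer can only add deficits, so every delta is")
print(">= 0; the upward-reclassified share shows how strongly the variant")
print("choice moves individual severity labels even when the mean shift is small.")
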