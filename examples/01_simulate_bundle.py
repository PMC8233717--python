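"""Generate a synthetic claims bundle with known ground truth.

The generator draws a latent frailty severity per patient, converts it into
31 deficit indicators, and emits dated, coded events (diagnoses, pharmacy
treatments, labs, hospitalizations) split across a VA-like and a CMS-like
payer.  The truth table records what was planted, so downstream stages can
be checked exactly.
"""

from efimm import SimulationConfig, simulate_cohort

bundle, truth = simulate_cohort(SimulationConfig(n_patients=500, seed=7))

print(f"patients: {len(bundle.patients)}")
print(f"coded events: {len(bundle.events)}")
print(f"lab results: {len(bundle.labs)}")
print()
print("true frailty-index distribution (proportion of 31 deficits present):")
print(truth.table["true_fi"].describe().round(3).to_string())
print()
counts = truth.table["true_category"].value_counts(normalize=True).sort_index()
labels = ["non-frail", "pre-frail", "mildly frail", "moderately frail", "severely frail"]
for cat, label in enumerate(labels):
    print(f"  {label:18s} {100 * counts.get(cat, 0.0):5.1f}%")
print()
print("Each row is the share of simulated patients whose *true* deficit count")
print("falls in that severity band; the scoring engine should recover these.")
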