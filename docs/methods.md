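# Methods

## The frailty index

The index is a deficit-accumulation score: a fixed catalog of 31
aging-related health deficits (morbidity 14, function 8, cognition & mood 3,
sensory 3, other 3), each mapped to diagnosis/procedure code patterns with
`prefix` or `exact` match rules on normalized codes (dots stripped,
upper-cased, so dotted and undotted ICD dialects match identically).  A
deficit is present if at least one event matches a mapping, falls inside the
measurement window, and carries an allowed payer source; repeat hits and
hits in both sources count once.  The score is F = d/31 with the fixed
catalog denominator — no per-patient eligible-item adjustment, since the
index is defined as the proportion of *possible* deficits.  Severity
categories use upper-inclusive cut-points at 0.1/0.2/0.3/0.4.

Measurement conventions that were genuinely open and are pinned here:

* **Window boundaries.** The lookback window is the half-open interval
  `(index − 365·W days, index]`, index date inclusive: the index is a
  baseline status at treatment initiation, so codes on the initiation date
  itself count, while a code exactly `365·W` days earlier does not.  W = 3
  by default, 1 as a variant.  Both ends are configurable.
* **Single-hit rule.** One qualifying code suffices for a deficit; no
  ≥2-hit confirmation rule is applied.
* **Nonstandard catalogs.** Catalogs with ≠31 items load with a warning and
  use their own denominator; the severity cut-points are unchanged because
  deficit-accumulation indices are denominator-relative.
* **Cancer is an ordinary deficit.** MM diagnosis codes map to it like any
  other mapping; its presence is not forced.

The shipped catalog's code vocabulary is **synthetic** — one representative
ICD-9-style and ICD-10-style prefix per deficit — sufficient for simulation
and testing.  Real deployments load validated code lists through the same
schema.

## Cohort selection

Criteria are evaluated per patient in a fixed order (diagnosis count →
index date → index-year range → age → utilization → washout → positive
follow-up); the first failure is the recorded exclusion reason and drives
the attrition table.  Conventions:

* "six months" is 183 days everywhere (treatment pair and washout);
* the three utilization "years" are consecutive 365-day blocks anchored at
  the index date, `[index − 365k, index − 365(k−1))`, not calendar years;
* age at index uses exact day counts / 365.25 with threshold ≥ 65.0;
* MM diagnosis dates are not required to precede the index date (the
  criterion counts observed dates; a `require_dx_before_index` switch
  exists);
* patients whose death is on or before the index date are excluded
  (`nonpositive_followup`) because survival time must be positive — a
  convention of this implementation, exposed as a criterion flag.

## Covariates

Labs use a 90-day window closing at the index date (the upper bound is a
choice: a baseline covariate must predate follow-up; configurable), latest
value wins, same-date ties resolved by load order with a logged warning.
ISS staging uses the standard external definition (β2M < 3.5 mg/L with
albumin ≥ 3.5 g/dL → stage I; β2M ≥ 5.5 → stage III; otherwise stage II),
including the logical consequence that stage III is derivable from β2M
alone with missing albumin, which reduces artificial missingness.
Treatment year enters models as a continuous covariate (switchable).
Induction agents are pharmacy codes in `[index, index + 90 days]`; novel
therapy is any of bortezomib/carfilzomib/ixazomib/thalidomide/lenalidomide/
pomalidomide; steroids are ignored.

## Survival analysis

Death: time from index to death, censored at min(last record, 2019-06-30).
Hospitalization: first VA inpatient admission flagged unplanned after
index, censored at min(death, last record, cutoff) — death is treated as
censoring, matching the measurement design; cumulative-incidence competing-
risk estimation is out of scope.

Kaplan–Meier estimation, Greenwood variance with log(−log) confidence
bands and median CIs from the band crossing of 0.5, delegates to
lifelines; k-sample log-rank to lifelines' multivariate test.  The Cox
partial likelihood is maximized by statsmodels' PHReg, chosen because it
exposes both Efron (package default) and Breslow tie handling; fits with
non-finite or absurd (|log HR| > 50) estimates raise an explicit
convergence error rather than returning silently.  Constant covariates are
excluded with a warning.  Test fixtures pin both backends against
independent oracles (hand Newton–Raphson partial-likelihood maximization,
the classic O−E/V log-rank sums, hand-computed product-limit steps), so a
backend change would be caught numerically.

Missing baseline covariates (ISS stage, lab flags) are multiply imputed
with chained equations via statsmodels' MICEData using predictive-mean
matching: imputed values are drawn from observed donors, so binary flags
stay binary and stages stay on {1,2,3}.  m = 20 imputations by default
(m is configurable; the no-missingness case short-circuits to identical
copies), pooled by Rubin's rules (mean log-HR; total variance = within +
(1 + 1/m)·between).  MICEData draws from numpy's global RandomState; the
implementation seeds and restores that state around the update loop so
imputations are reproducible and isolated.  Sensitivity reruns refit the
adjusted model on the 2012–2017 index-year subset and on complete cases.

## Variant comparison

Paired per-patient deltas (comparator − baseline) over the identical
patient set; two-sided one-sample t-test of zero mean change; the
all-zero-delta degenerate case reports p = 1 with a flag instead of
failing.  Reclassification is counted on the five-level severity scale
(not the binary frail cut), and the "large change" threshold defaults to
0.1 — a clinically meaningful frailty-index change — as a parameter.
Because source sets and windows nest, VA→VA+CMS and 1y→3y comparisons have
all deltas ≥ 0 by construction, which the tests assert as an invariant.

## Synthetic-EHR generator

The generator defines the study conditions for all simulation-based tests:

* latent frailty q ~ Beta(10, 12.5); deficit j present with probability
  expit(α_j + β·logit q), conditionally independent given q (single-factor
  model — the simplest structure that yields a graded
  prevalence-by-severity profile).  β = 1.5; the α_j are solved by
  quadrature + root-finding so marginal prevalences hit per-deficit targets
  taken from a treated older MM population (hypertension 88.9%, anemia
  73.7%, cancer 97.7%, …, failure-to-thrive 1.7%).  These latent-shape
  choices make the simulated severity distribution (≈4/22/34/23/16% across
  the five categories, median F 0.29, IQR 0.19–0.35) resemble such a
  cohort;
* each true deficit emits ≥1 coded event inside the 3-year window (dates
  uniform by default; a point-mass option supports boundary tests), payer
  CMS with probability `source_split` (default 0.25), else VA;
* MM streams: ≥3 diagnosis dates (ICD-9 before the 2015-10 code switch,
  ICD-10 after), first/second treatment dispenses with a log-normal gap
  (median 11 days, clipped to [1, 180]), induction agent novel with
  probability 0.859; MM diagnosis dates are placed inside the lookback
  window only when the cancer deficit is truly present, so catalog scoring
  recovers the planted deficit sets exactly;
* death and hospitalization times are Weibull proportional-hazards draws
  by inverse CDF (closed form), with log-hazard increments monotone in true
  severity — death ladder (0, 0.285, 0.565, 0.854, 1.135), i.e. HRs
  1.33/1.76/2.35/3.11, baseline scale 7.9 y; hospitalization ladder
  (0, 0.351, 0.542, 0.599, 0.747), scale 2.2 y — independent given
  category, with administrative censoring at 2019-06-30;
* labs are drawn with severity-dependent means and per-analyte missingness
  (β2-microglobulin most often missing, 55%, so ISS stage is frequently
  unstageable, as in real claims data);
* `exclusion_fractions` plants disjoint patient subsets violating one
  cohort criterion each (recorded in the truth table); all zero by default.

Randomness flows through named substreams spawned from one seed
(frailty/deficits/index/survival and demographics/placement/mm/labs/decoys/
exclusions), so identical configs are byte-reproducible and toggling one
component does not perturb the others.

What the generator does **not** emulate: realistic ICD code frequencies or
coding drift across calendar years, billing artifacts, correlated deficit
clusters beyond the single factor, informative (non-administrative)
censoring, external hospitalizations, transplant patients, or cytogenetics.
Passing recovery tests therefore demonstrates that the pipeline measures
and models correctly *under its stated assumptions*; they do not validate
the index against in-person frailty assessment or real claims data.

## Problem sizes and numerical choices

Property suites run at sizes chosen to make their tolerances meaningful:
marginal-prevalence calibration at n = 1000 with a 3·SE binomial band;
log-rank type-I error over 500 replicates of n = 200 (nominal 0.05,
accepted band [0.03, 0.07] ≈ ±2 SE); Cox hazard-ratio recovery over 200
replicates at n = 4000 (true HR 2.0, within 15% in ≥90% of replicates);
category-HR monotonicity over 100 seeds at n = 4000 run on the generator's
truth + survival stages directly (coded-event placement does not affect the
hazard model given true categories).  Simulated event times are continuous,
so Breslow and Efron tie handling coincide in these suites and the faster
Breslow path is used; fixture tests exercise both.  All replicate suites
use fixed seeds.
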