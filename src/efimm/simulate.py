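"""Synthetic claims/EHR cohort generator with known ground truth.

Restricted clinical data cannot ship with an analysis pipeline, so every
downstream stage is exercised on simulated bundles whose truth is recorded:

* a per-patient latent frailty severity ``q ~ Beta(a, b)`` on (0, 1);
* 31 deficit indicators drawn conditionally independently given ``q`` from a
  single-factor logistic model, ``P(deficit j) = expit(alpha_j + beta_j *
  logit(q))``; intercepts are calibrated numerically so marginal prevalences
  hit configurable targets (defaults emulate the graded prevalence profile
  of a treated myeloma population: hypertension ~89%, anemia ~74%, ...,
  failure-to-thrive ~2%);
* one-or-more dated coded events per true deficit inside the 3-year lookback,
  each assigned to the CMS payer with probability ``source_split``;
* multiple-myeloma diagnosis and pharmacy treatment streams that define the
  index date (first treatment code, second within 183 days — median gap ~11
  days);
* death and first-unplanned-hospitalization times from Weibull
  proportional-hazards models whose log-hazard increments are monotone in
  the true severity category (defaults follow the unadjusted dose–response
  ladder HR 1.33/1.76/2.35/3.11 for death and 1.42/1.72/1.82/2.11 for
  hospitalization), administratively censored at 2019-06-30;
* labs correlated with latent severity, with realistic missingness (B2M most
  often absent, so ISS stage is frequently unstageable).

All randomness flows through named ``numpy`` substreams spawned from one
seed, so toggling one component leaves the others untouched and identical
configs reproduce byte-identical bundles.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .catalog import DeficitCatalog, default_catalog
from .model import (
    AdmissionType,
    Analyte,
    CareSetting,
    CodedEvent,
    CodeSystem,
    EventBundle,
    LabResult,
    PatientRecord,
    Race,
    Sex,
    Source,
)

__all__ = [
    "WeibullPH",
    "SimulationConfig",
    "TruthTable",
    "ConfigError",
    "DEFAULT_PREVALENCE_TARGETS",
    "calibrate_intercepts",
    "simulate_truth",
    "simulate_event_times",
    "simulate_survival",
    "place_coded_events",
    "simulate_cohort",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# Marginal prevalence targets (fraction of cohort with each deficit);
# calibration targets for the deficit intercepts.  Profile of a treated
# older myeloma population: near-universal cancer/hypertension codes, very
# rare failure-to-thrive.
DEFAULT_PREVALENCE_TARGETS: dict[str, float] = {
    "atrial_fibrillation": 0.188,
    "anemia": 0.737,
    "cad": 0.421,
    "cancer": 0.977,
    "cvd": 0.202,
    "ckd": 0.415,
    "diabetes": 0.410,
    "heart_failure": 0.232,
    "hypertension": 0.889,
    "liver_disease": 0.110,
    "lung_disease": 0.361,
    "thyroid_disease": 0.150,
    "osteoporosis": 0.171,
    "incontinence": 0.079,
    "arthritis": 0.559,
    "dme": 0.224,
    "falls": 0.112,
    "fatigue": 0.259,
    "gait_abnormality": 0.207,
    "muscular_impairment": 0.191,
    "parkinsons": 0.031,
    "pvd": 0.307,
    "dementia": 0.139,
    "anxiety": 0.126,
    "depression": 0.235,
    "peripheral_neuropathy": 0.118,
    "hearing_impairment": 0.344,
    "vision_impairment": 0.307,
    "chronic_pain": 0.288,
    "failure_to_thrive": 0.017,
    "weight_loss": 0.121,
}


@dataclass(frozen=True)
class WeibullPH:
    """Weibull baseline hazard with proportional category effects.

    Survival time for category ``c``: ``T = scale * (-ln U / exp(lp_c))^(1/shape)``
    with ``lp_c`` the category's log-hazard increment — inverse-CDF sampling
    from S(t) = exp(-(t/scale)^shape * exp(lp_c)).
    """

    shape: float = 1.0
    scale: float = 7.9  # years; baseline (non-frail) median ~5.5 y when shape=1
    log_hr_by_category: tuple[float, ...] = (0.0, 0.285, 0.565, 0.854, 1.135)

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.shape <= 0:
            raise ConfigError("Weibull shape and scale must be positive")
        if not all(math.isfinite(x) for x in self.log_hr_by_category):
            raise ConfigError("hazard increments must be finite")


DEFAULT_HOSP_HAZARD = WeibullPH(
    shape=1.0,
    scale=2.2,
    log_hr_by_category=(0.0, 0.351, 0.542, 0.599, 0.747),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; defaults define the study conditions.

    ``deficit_loading`` maps deficit id -> (intercept, slope) on the log-odds
    scale; ``None`` means "calibrate intercepts to ``prevalence_targets``
    with slope ``default_slope``".  ``window_scatter`` is either ``"uniform"``
    (uniform over the 3-year window) or ``("point", days_before_index)``.
    ``exclusion_fractions`` deliberately plants patients violating each
    cohort criterion (all zero by default).
    """

    n_patients: int = 1000
    seed: int = 0
    latent_beta: tuple[float, float] = (10.0, 12.5)
    deficit_loading: dict[str, tuple[float, float]] | None = None
    default_slope: float = 1.5
    prevalence_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_TARGETS)
    )
    source_split: float = 0.25  # P(event emitted under CMS rather than VA)
    window_scatter: object = "uniform"
    window_years: int = 3
    treatment_gap_median_days: float = 11.0
    treatment_gap_sigma: float = 0.9
    novel_therapy_rate: float = 0.859
    hazard_model: WeibullPH = WeibullPH()
    hosp_hazard_model: WeibullPH = DEFAULT_HOSP_HAZARD
    censor_date: dt.date = dt.date(2019, 6, 30)
    index_start: dt.date = dt.date(2004, 1, 1)
    index_end: dt.date = dt.date(2017, 12, 31)
    decoy_rate: float = 0.0  # mean decoy (unmapped) codes per patient
    lab_missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "albumin": 0.15,
            "beta2_microglobulin": 0.55,
            "calcium": 0.09,
            "creatinine": 0.07,
            "hemoglobin": 0.07,
            "platelets": 0.13,
        }
    )
    exclusion_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a, b = self.latent_beta
        if a <= 0 or b <= 0:
            raise ConfigError(f"Beta parameters must be positive, got ({a}, {b})")
        if not (0.0 <= self.source_split <= 1.0):
            raise ConfigError("source_split must be in [0, 1]")
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        for frac in self.exclusion_fractions.values():
            if not (0.0 <= frac <= 1.0):
                raise ConfigError("exclusion fractions must be in [0, 1]")


@dataclass
class TruthTable:
    """Simulator ground truth for recovery tests.

    ``table`` has one row per patient: latent_frailty, n_deficits, true_fi,
    true_category (0..4), index_date, event times in years from index, and
    whether the patient was planted to violate a cohort criterion.
    ``deficits`` maps patient id -> frozenset of true deficit ids.
    """

    table: pd.DataFrame
    deficits: dict[str, frozenset[str]]

    def category(self, patient_id: str) -> int:
        return int(self.table.loc[patient_id, "true_category"])


SEVERITY_EDGES = (0.1, 0.2, 0.3, 0.4)


def _category_from_fi(fi: np.ndarray) -> np.ndarray:
    cat = np.zeros(len(fi), dtype=int)
    for edge in SEVERITY_EDGES:
        cat += (fi > edge).astype(int)
    return cat


def calibrate_intercepts(
    targets: dict[str, float],
    slope: float,
    latent_beta: tuple[float, float],
    n_grid: int = 400,
) -> dict[str, tuple[float, float]]:
    """Solve per-deficit intercepts so marginal prevalence hits its target.

    With q ~ Beta(a, b) and z = logit(q), finds alpha such that
    E[expit(alpha + slope * z)] = target, via Gauss–Legendre quadrature over
    the Beta density and Brent root-finding.  Exact in the large-n limit; at
    finite n the empirical prevalence fluctuates binomially around the
    target.
    """
    a, b = latent_beta
    nodes, weights = np.polynomial.legendre.leggauss(n_grid)
    q = 0.5 * (nodes + 1.0)  # (0, 1)
    w = 0.5 * weights
    from scipy.stats import beta as beta_dist

    dens = beta_dist.pdf(q, a, b)
    z = logit(q)

    def marginal(alpha: float) -> float:
        return float(np.sum(w * dens * expit(alpha + slope * z)))

    loading = {}
    for deficit_id, target in targets.items():
        if not (0.0 < target < 1.0):
            raise ConfigError(f"prevalence target for {deficit_id} must be in (0,1)")
        alpha = brentq(lambda x: marginal(x) - target, -40.0, 40.0)
        loading[deficit_id] = (float(alpha), slope)
    return loading


def _resolve_loading(
    config: SimulationConfig, catalog: DeficitCatalog
) -> dict[str, tuple[float, float]]:
    if config.deficit_loading is not None:
        missing = set(catalog.deficit_ids) - set(config.deficit_loading)
        if missing:
            raise ConfigError(f"deficit_loading missing deficits: {sorted(missing)}")
        return config.deficit_loading
    targets = {d: config.prevalence_targets[d] for d in catalog.deficit_ids}
    return calibrate_intercepts(targets, config.default_slope, config.latent_beta)


def simulate_event_times(
    categories: np.ndarray, model: WeibullPH, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized Weibull-PH event times (years) for true categories."""
    lp = np.asarray(model.log_hr_by_category)[np.asarray(categories, dtype=int)]
    u = rng.uniform(size=len(categories))
    return model.scale * (-np.log(u) / np.exp(lp)) ** (1.0 / model.shape)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_truth(config: SimulationConfig, catalog: DeficitCatalog | None = None) -> TruthTable:
    """Latent frailty, true deficits, categories, index dates and event times.

    This is the statistical core of the generator; coded-event placement and
    demographics live in :func:`simulate_cohort`.
    """
    catalog = catalog or default_catalog()
    (rng_frailty, rng_deficits, rng_index, rng_survival) = _spawn(config.seed, 4)

    n = config.n_patients
    ids = [f"P{i:06d}" for i in range(n)]
    a, b = config.latent_beta
    q = rng_frailty.beta(a, b, size=n)
    q = np.clip(q, 1e-9, 1 - 1e-9)
    z = logit(q)

    loading = _resolve_loading(config, catalog)
    deficit_ids = catalog.deficit_ids
    present = np.zeros((n, len(deficit_ids)), dtype=bool)
    for j, did in enumerate(deficit_ids):
        alpha, slope = loading[did]
        if alpha == -math.inf:
            continue
        p = expit(alpha + slope * z)
        present[:, j] = rng_deficits.uniform(size=n) < p

    d = present.sum(axis=1)
    fi = d / len(deficit_ids)
    cat = _category_from_fi(fi)

    # index dates: first treatment uniform over the study years
    span = (config.index_end - config.index_start).days
    offsets = rng_index.integers(0, span + 1, size=n)
    index_dates = [config.index_start + dt.timedelta(days=int(o)) for o in offsets]
    gaps = np.clip(
        np.round(
            rng_index.lognormal(
                math.log(config.treatment_gap_median_days),
                config.treatment_gap_sigma,
                size=n,
            )
        ),
        1,
        180,
    ).astype(int)

    death_t = simulate_event_times(cat, config.hazard_model, rng_survival)
    hosp_t = simulate_event_times(cat, config.hosp_hazard_model, rng_survival)

    deficits = {
        pid: frozenset(did for j, did in enumerate(deficit_ids) if present[i, j])
        for i, pid in enumerate(ids)
    }
    table = pd.DataFrame(
        {
            "patient_id": ids,
            "latent_frailty": q,
            "n_deficits": d,
            "true_fi": fi,
            "true_category": cat,
            "index_date": index_dates,
            "treatment_gap_days": gaps,
            "death_time_years": death_t,
            "hosp_time_years": hosp_t,
            "planted_exclusion": [""] * n,
        }
    ).set_index("patient_id", drop=False)
    return TruthTable(table=table, deficits=deficits)


def simulate_survival(
    truth: TruthTable, hazard_model: WeibullPH, rng: np.random.Generator
) -> pd.DataFrame:
    """Redraw death/hospitalization times for an existing truth table.

    Returns a frame with death/hospitalization dates and the administrative
    censoring flag implied by each patient's index date; used when survival
    must be re-simulated under an alternative hazard model.
    """
    cats = truth.table["true_category"].to_numpy()
    times = simulate_event_times(cats, hazard_model, rng)
    out = truth.table[["patient_id", "index_date"]].copy()
    out["event_time_years"] = times
    return out


def _window_days(config: SimulationConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """Days before index for deficit codes, per the window_scatter setting."""
    max_days = 365 * config.window_years - 1
    if config.window_scatter == "uniform":
        return rng.integers(0, max_days + 1, size=size)
    if (
        isinstance(config.window_scatter, tuple)
        and len(config.window_scatter) == 2
        and config.window_scatter[0] == "point"
    ):
        return np.full(size, int(config.window_scatter[1]))
    raise ConfigError(f"unknown window_scatter {config.window_scatter!r}")


def place_coded_events(
    truth: TruthTable,
    catalog: DeficitCatalog,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[CodedEvent]:
    """Deficit-qualifying coded events: >= 1 per true deficit inside the
    lookback window, payer assigned VA/CMS by ``source_split``."""
    for item in catalog.items:
        if not item.mappings:
            raise ConfigError(f"catalog deficit {item.deficit_id} has empty mapping")
    events: list[CodedEvent] = []
    for pid in truth.table.index:
        index_date = truth.table.loc[pid, "index_date"]
        for did in sorted(truth.deficits[pid]):
            item = catalog.item(did)
            n_hits = 1 + rng.poisson(0.5)
            days = _window_days(config, rng, n_hits)
            for day in days:
                mapping = item.mappings[int(rng.integers(0, len(item.mappings)))]
                code = mapping.pattern
                if mapping.match_rule == "prefix":
                    # cancer prefixes extend with nonzero digits so generated
                    # codes never collide with the MM diagnosis prefixes
                    # (203.0 / C90.0), which carry cohort-selection meaning
                    lo_digit = 1 if code.replace(".", "").upper() in ("203", "C90") else 0
                    code = f"{code}{rng.integers(lo_digit, 10)}"
                source = Source.CMS if rng.uniform() < config.source_split else Source.VA
                events.append(
                    CodedEvent(
                        patient_id=pid,
                        event_date=index_date - dt.timedelta(days=int(day)),
                        code=code,
                        code_system=mapping.code_system,
                        source=source,
                        care_setting=CareSetting.OUTPATIENT,
                    )
                )
    return events


_RACE_PROBS = [(Race.WHITE, 0.665), (Race.BLACK, 0.227), (Race.OTHER, 0.013), (Race.MISSING, 0.095)]
_NOVEL = ["lenalidomide", "bortezomib", "thalidomide", "carfilzomib", "ixazomib", "pomalidomide"]
_NOVEL_W = [0.38, 0.40, 0.14, 0.04, 0.02, 0.02]


def _lab_value(analyte: Analyte, q: float, rng: np.random.Generator) -> float:
    if analyte is Analyte.ALBUMIN:
        return float(np.clip(rng.normal(4.0 - 0.8 * q, 0.45), 1.5, 5.5))
    if analyte is Analyte.BETA2_MICROGLOBULIN:
        return float(np.exp(rng.normal(math.log(3.0) + 1.0 * q, 0.5)))
    if analyte is Analyte.CALCIUM:
        return float(np.clip(rng.normal(9.6 + 0.6 * q, 0.7), 6.0, 16.0))
    if analyte is Analyte.CREATININE:
        return float(np.exp(rng.normal(math.log(1.2) + 0.5 * q, 0.4)))
    if analyte is Analyte.HEMOGLOBIN:
        return float(np.clip(rng.normal(11.5 - 2.0 * q, 1.6), 4.0, 18.0))
    return float(np.clip(rng.normal(220 - 60 * q, 60), 10.0, 800.0))


def simulate_cohort(
    config: SimulationConfig, catalog: DeficitCatalog | None = None
) -> tuple[EventBundle, TruthTable]:
    """Full generator: truth, demographics, coded streams, labs, survival.

    Deterministic given ``config.seed``.  With ``exclusion_fractions`` all
    zero (the default) every patient satisfies the cohort criteria; each
    configured fraction plants a disjoint subset of patients violating one
    criterion, recorded in the truth table's ``planted_exclusion`` column.
    """
    catalog = catalog or default_catalog()
    truth = simulate_truth(config, catalog)
    (rng_demo, rng_place, rng_mm, rng_labs, rng_decoy, rng_excl) = _spawn(
        config.seed + 1_000_003, 6
    )
    n = config.n_patients
    ids = list(truth.table.index)

    # --- planted criterion violations (disjoint slices of a shuffled order)
    order = list(rng_excl.permutation(n))
    planted: dict[str, str] = {}
    pos = 0
    for reason, frac in sorted(config.exclusion_fractions.items()):
        k = int(round(frac * n))
        for i in order[pos : pos + k]:
            planted[ids[i]] = reason
        pos += k
    truth.table["planted_exclusion"] = [planted.get(pid, "") for pid in ids]

    # --- deficit events
    events = place_coded_events(truth, catalog, config, rng_place)

    patients: list[PatientRecord] = []
    labs: list[LabResult] = []
    use_icd10 = lambda index_date: index_date >= dt.date(2015, 10, 1)

    for i, pid in enumerate(ids):
        row = truth.table.loc[pid]
        index_date: dt.date = row["index_date"]
        reason = planted.get(pid, "")
        q = float(row["latent_frailty"])

        if reason == "index_year_out_of_range":
            # shift this patient's whole timeline before the study years
            shift = dt.timedelta(days=365 * (index_date.year - 2001))
            index_date = index_date - shift
            truth.table.at[pid, "index_date"] = index_date
            events = [
                e if e.patient_id != pid else replace_date(e, e.event_date - shift)
                for e in events
            ]

        # demographics
        age = float(np.clip(65.0 + rng_demo.gamma(2.2, 4.8), 65.1, 100.0))
        if reason == "age_below_minimum":
            age = 60.0
        birth_date = index_date - dt.timedelta(days=int(round(age * 365.25)))
        sex = Sex.M if rng_demo.uniform() < 0.986 else Sex.F
        u = rng_demo.uniform()
        acc = 0.0
        race = Race.WHITE
        for r, p in _RACE_PROBS:
            acc += p
            if u < acc:
                race = r
                break
        income = float(np.round(np.exp(rng_demo.normal(math.log(27500), 0.6)), 2))

        # MM diagnosis dates: 3 distinct dates; inside the lookback window only
        # if the cancer deficit is truly present (so scoring matches truth)
        n_dx = 2 if reason == "insufficient_mm_dx_dates" else 3
        if "cancer" in truth.deficits[pid]:
            lo_day, hi_day = 0, 365 * config.window_years - 1
        else:
            lo_day, hi_day = 365 * config.window_years + 30, 365 * (config.window_years + 3)
        dx_days = set()
        while len(dx_days) < n_dx:
            dx_days.add(int(rng_mm.integers(lo_day, hi_day + 1)))
        icd10 = use_icd10(index_date)
        for day in sorted(dx_days):
            events.append(
                CodedEvent(
                    patient_id=pid,
                    event_date=index_date - dt.timedelta(days=day),
                    code="C90.0" + str(rng_mm.integers(0, 3)) if icd10 else "203.0" + str(rng_mm.integers(0, 2)),
                    code_system=CodeSystem.ICD10 if icd10 else CodeSystem.ICD9,
                    source=Source.CMS if rng_mm.uniform() < config.source_split else Source.VA,
                    care_setting=CareSetting.OUTPATIENT,
                )
            )

        # treatment stream: agent at index and at index + gap
        novel = rng_mm.uniform() < config.novel_therapy_rate
        agent = (
            _NOVEL[int(rng_mm.choice(len(_NOVEL), p=np.array(_NOVEL_W) / sum(_NOVEL_W)))]
            if novel
            else "melphalan"
        )
        gap = int(row["treatment_gap_days"])
        if reason == "no_index_date":
            tx_dates = [index_date]
        else:
            tx_dates = [index_date, index_date + dt.timedelta(days=gap)]
        for td in tx_dates:
            events.append(
                CodedEvent(
                    patient_id=pid,
                    event_date=td,
                    code=agent,
                    code_system=CodeSystem.RX,
                    source=Source.VA,
                    care_setting=CareSetting.OUTPATIENT,
                )
            )
        if reason == "cms_washout":
            events.append(
                CodedEvent(
                    patient_id=pid,
                    event_date=index_date - dt.timedelta(days=100),
                    code=agent,
                    code_system=CodeSystem.RX,
                    source=Source.CMS,
                    care_setting=CareSetting.OUTPATIENT,
                )
            )

        # VA utilization fillers: one wellness code per lookback year-block
        skip_block = 2 if reason == "insufficient_va_utilization" else None
        for k in range(1, 4):
            if k == skip_block:
                continue
            day = int(rng_mm.integers(365 * (k - 1), 365 * k))
            events.append(
                CodedEvent(
                    patient_id=pid,
                    event_date=index_date - dt.timedelta(days=day),
                    code="Z00.0",
                    code_system=CodeSystem.ICD10,
                    source=Source.VA,
                    care_setting=CareSetting.OUTPATIENT,
                )
            )
        if skip_block is not None:
            # move any VA deficit codes out of the skipped block to CMS so the
            # utilization criterion genuinely fails while deficits stay codeable
            lo = index_date - dt.timedelta(days=365 * skip_block)
            hi = index_date - dt.timedelta(days=365 * (skip_block - 1))
            events = [
                replace_source(e, Source.CMS)
                if (
                    e.patient_id == pid
                    and e.source is Source.VA
                    and lo <= e.event_date < hi
                    and e.code_system is not CodeSystem.RX
                )
                else e
                for e in events
            ]

        # decoy codes mapping to no deficit
        for _ in range(rng_decoy.poisson(config.decoy_rate)):
            day = int(rng_decoy.integers(0, 365 * config.window_years))
            events.append(
                CodedEvent(
                    patient_id=pid,
                    event_date=index_date - dt.timedelta(days=day),
                    code="Z13.9",
                    code_system=CodeSystem.ICD10,
                    source=Source.CMS if rng_decoy.uniform() < config.source_split else Source.VA,
                    care_setting=CareSetting.OUTPATIENT,
                )
            )

        # survival: death date, hospitalization event, administrative censoring
        death_days = max(1, int(round(float(row["death_time_years"]) * 365.25)))
        death_date = index_date + dt.timedelta(days=death_days)
        observed_death = death_date <= config.censor_date
        last_activity = min(death_date, config.censor_date)
        hosp_days = max(1, int(round(float(row["hosp_time_years"]) * 365.25)))
        hosp_date = index_date + dt.timedelta(days=hosp_days)
        if hosp_date <= last_activity and hosp_date <= config.censor_date:
            events.append(
                CodedEvent(
                    patient_id=pid,
                    event_date=hosp_date,
                    code="Z99.8",
                    code_system=CodeSystem.ICD10,
                    source=Source.VA,
                    care_setting=CareSetting.INPATIENT,
                    admission_type=AdmissionType.UNPLANNED,
                )
            )

        patients.append(
            PatientRecord(
                patient_id=pid,
                birth_date=birth_date,
                sex=sex,
                race=race,
                income=income,
                last_activity_date=last_activity,
                death_date=death_date if observed_death else None,
            )
        )

        # labs in the 90-day pre-index window
        for analyte in Analyte:
            if rng_labs.uniform() < config.lab_missing_rates.get(analyte.value, 0.0):
                continue
            labs.append(
                LabResult(
                    patient_id=pid,
                    date=index_date - dt.timedelta(days=int(rng_labs.integers(0, 91))),
                    analyte=analyte,
                    value=float(np.round(_lab_value(analyte, q, rng_labs), 3)),
                )
            )

    bundle = EventBundle(patients=patients, events=events, labs=labs)
    return bundle, truth


def replace_date(e: CodedEvent, new_date: dt.date) -> CodedEvent:
    return CodedEvent(
        patient_id=e.patient_id,
        event_date=new_date,
        code=e.code,
        code_system=e.code_system,
        source=e.source,
        care_setting=e.care_setting,
        admission_type=e.admission_type,
    )


def replace_source(e: CodedEvent, new_source: Source) -> CodedEvent:
    return CodedEvent(
        patient_id=e.patient_id,
        event_date=e.event_date,
        code=e.code,
        code_system=e.code_system,
        source=new_source,
        care_setting=e.care_setting,
        admission_type=e.admission_type,
    )
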