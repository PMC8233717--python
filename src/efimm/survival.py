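"""Outcome construction and survival statistics.

Two outcomes are built from an event bundle and cohort decisions:

* overall survival — time from the index date to death, administratively
  censored at the study cutoff (2019-06-30 by default) or the patient's last
  record, whichever is earlier;
* time to first unplanned hospitalization — first VA inpatient admission
  flagged unplanned after the index date, censoring at death, last record or
  the cutoff (death treated as censoring, not a competing risk).

Estimators: Kaplan–Meier curves (Greenwood variance, log-log confidence
intervals, medians with CIs), k-sample log-rank tests, and Cox proportional
hazards models with Efron (default) or Breslow tie handling.  Missing
baseline covariates are handled by chained-equations multiple imputation with
Rubin's-rules pooling; complete-case and 2012–2017 subset reruns are provided
as sensitivity analyses.

Kaplan–Meier and log-rank delegate to lifelines; the Cox partial likelihood
is maximized by statsmodels' PHReg (which exposes both tie methods).  Test
fixtures pin the numeric behavior of both backends against hand-computed
oracles.
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .cohort import CohortDecision
from .covariates import BaselineCovariates
from .frailty import FrailtyScore, Severity
from .model import AdmissionType, CareSetting, EventBundle, Source

__all__ = [
    "OutcomeType",
    "SurvivalRecord",
    "KMCurve",
    "CoxResult",
    "ImputationSet",
    "ConvergenceError",
    "DEFAULT_CUTOFF",
    "build_survival_records",
    "records_frame",
    "km_estimate",
    "logrank",
    "cox_fit",
    "mice_impute",
    "pool",
    "cox_fit_mice",
    "sensitivity_reruns",
    "CATEGORY_COLUMNS",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = dt.date(2019, 6, 30)
DAYS_PER_YEAR_EXACT = 365.25


class ConvergenceError(RuntimeError):
    """The partial-likelihood maximization failed (e.g. separation)."""


class OutcomeType(str, enum.Enum):
    DEATH = "death"
    HOSPITALIZATION = "first_unplanned_hospitalization"


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # years from index, > 0
    event: int  # 1 = died / hospitalized, 0 = censored
    outcome_type: OutcomeType
    category: Severity

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"patient {self.patient_id}: nonpositive follow-up")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class KMCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]
    horizons: dict[float, tuple[float, float, float]]  # t -> (S, lo, hi)
    n: int
    n_events: int


@dataclass
class CoxResult:
    """Per-covariate estimates from a proportional-hazards fit."""

    table: pd.DataFrame  # index: covariate; columns: log_hr, se, hr, ci_lower, ci_upper
    log_likelihood: float
    ties: str
    n: int
    n_events: int
    dropped: list[str] = field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def log_hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "log_hr"])


@dataclass
class ImputationSet:
    """m completed covariate tables from chained-equations imputation."""

    completed: list[pd.DataFrame]
    seed: int

    @property
    def m(self) -> int:
        return len(self.completed)


def _years(d0: dt.date, d1: dt.date) -> float:
    return (d1 - d0).days / DAYS_PER_YEAR_EXACT


def build_survival_records(
    bundle: EventBundle,
    decisions: list[CohortDecision],
    outcome_type: OutcomeType,
    scores: dict[str, FrailtyScore],
    cutoff_date: dt.date = DEFAULT_CUTOFF,
) -> list[SurvivalRecord]:
    """One record per included patient; nonpositive follow-up is dropped
    with a logged reason."""
    events_by = bundle.events_by_patient()
    records: list[SurvivalRecord] = []
    for decision in decisions:
        if not decision.included:
            continue
        patient = bundle.patient(decision.patient_id)
        index = decision.index_date
        assert index is not None
        death = patient.death_date
        admin_end = min(patient.last_activity_date, cutoff_date)

        if outcome_type is OutcomeType.DEATH:
            if death is not None and death <= cutoff_date:
                time, event = _years(index, death), 1
            else:
                time, event = _years(index, admin_end), 0
        else:
            censor_end = admin_end if death is None else min(death, admin_end)
            hosp_dates = [
                e.event_date
                for e in events_by[decision.patient_id]
                if e.source is Source.VA
                and e.care_setting is CareSetting.INPATIENT
                and e.admission_type is AdmissionType.UNPLANNED
                and e.event_date > index
            ]
            first_hosp = min(hosp_dates) if hosp_dates else None
            if first_hosp is not None and first_hosp <= censor_end:
                time, event = _years(index, first_hosp), 1
            else:
                time, event = _years(index, censor_end), 0

        if time <= 0:
            logger.warning(
                "patient %s: nonpositive %s follow-up (%.3f y); dropped",
                decision.patient_id,
                outcome_type.value,
                time,
            )
            continue
        records.append(
            SurvivalRecord(
                patient_id=decision.patient_id,
                time=time,
                event=event,
                outcome_type=outcome_type,
                category=scores[decision.patient_id].category,
            )
        )
    return records


CATEGORY_COLUMNS = [
    "fi_pre_frail",
    "fi_mild",
    "fi_moderate",
    "fi_severe",
]


def category_dummies(categories: pd.Series) -> pd.DataFrame:
    """Indicator contrasts versus the non-frail reference category."""
    out = pd.DataFrame(index=categories.index)
    for col, sev in zip(
        CATEGORY_COLUMNS,
        [Severity.PRE_FRAIL, Severity.MILD, Severity.MODERATE, Severity.SEVERE],
    ):
        out[col] = (categories == int(sev)).astype(float)
    return out


def records_frame(
    records: list[SurvivalRecord],
    covariates: dict[str, BaselineCovariates] | None = None,
) -> pd.DataFrame:
    """Long table of survival records, optionally joined with baseline
    covariates (missing values as NaN, race as explicit categories)."""
    rows = [
        {
            "patient_id": r.patient_id,
            "time": r.time,
            "event": r.event,
            "category": int(r.category),
        }
        for r in records
    ]
    df = pd.DataFrame(rows).set_index("patient_id")
    if covariates is not None:
        cov_rows = []
        for pid in df.index:
            c = covariates[pid]
            cov_rows.append(
                {
                    "patient_id": pid,
                    "age": c.age_at_index,
                    "male": 1.0 if c.sex.value == "M" else 0.0,
                    "race_black": 1.0 if c.race.value == "Black" else 0.0,
                    "race_other": 1.0 if c.race.value == "Other" else 0.0,
                    "race_missing": 1.0 if c.race.value == "Missing" else 0.0,
                    "income": np.nan if c.income is None else float(c.income),
                    "treatment_year": float(c.treatment_year),
                    "iss_stage": np.nan if c.iss_stage is None else float(c.iss_stage),
                    "ca_high": np.nan if c.ca_high is None else float(c.ca_high),
                    "cr_high": np.nan if c.cr_high is None else float(c.cr_high),
                    "hgb_low": np.nan if c.hgb_low is None else float(c.hgb_low),
                    "plt_low": np.nan if c.plt_low is None else float(c.plt_low),
                }
            )
        df = df.join(pd.DataFrame(cov_rows).set_index("patient_id"))
    return df


def encode_design(frame: pd.DataFrame, covariate_cols: list[str]) -> pd.DataFrame:
    """Design matrix from a (possibly imputed) record frame.

    ``category`` expands into indicator contrasts vs non-frail; ``iss_stage``
    into stage-2/-3 indicators vs stage 1.  All other columns pass through.
    """
    out = pd.DataFrame(index=frame.index)
    for col in covariate_cols:
        if col == "category":
            out = out.join(category_dummies(frame["category"]))
        elif col == "iss_stage":
            out["iss_2"] = (frame["iss_stage"] == 2).astype(float)
            out["iss_3"] = (frame["iss_stage"] == 3).astype(float)
        else:
            out[col] = frame[col].astype(float)
    return out


def km_estimate(
    records: list[SurvivalRecord],
    by_category: bool = True,
    horizons: tuple[float, ...] = (1.0, 5.0),
    alpha: float = 0.05,
) -> dict[str, KMCurve]:
    """Product-limit curves per group (or one pooled curve).

    Greenwood variance on the log(-log) scale; median CI from the crossing of
    the confidence band with 0.5; medians the curve never reaches are
    reported as ``None``.
    """
    if not records:
        raise ValueError("no records")
    groups: dict[str, list[SurvivalRecord]] = {}
    if by_category:
        for r in records:
            groups.setdefault(r.category.label, []).append(r)
    else:
        groups["all"] = list(records)

    out: dict[str, KMCurve] = {}
    for label in sorted(groups, key=lambda l: _label_order(l)):
        rs = groups[label]
        t = np.array([r.time for r in rs])
        e = np.array([r.event for r in rs])
        kmf = KaplanMeierFitter(alpha=alpha)
        kmf.fit(t, e, label=label)
        ci = kmf.confidence_interval_
        med = kmf.median_survival_time_
        med_ci_df = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(med_ci_df.iloc[0, 0]), float(med_ci_df.iloc[0, 1])
        horizon_est = {}
        for h in horizons:
            s = _step_lookup(kmf.survival_function_[label], h)
            cl = _step_lookup(ci.iloc[:, 0], h)
            cu = _step_lookup(ci.iloc[:, 1], h)
            horizon_est[h] = (s, cl, cu)
        out[label] = KMCurve(
            group=label,
            times=kmf.survival_function_.index.to_numpy(),
            survival=kmf.survival_function_[label].to_numpy(),
            ci_lower=ci.iloc[:, 0].to_numpy(),
            ci_upper=ci.iloc[:, 1].to_numpy(),
            median=None if np.isinf(med) else float(med),
            median_ci=(None if np.isinf(lo) else lo, None if np.isinf(hi) else hi),
            horizons=horizon_est,
            n=len(rs),
            n_events=int(e.sum()),
        )
    return out


def _label_order(label: str) -> int:
    for sev in Severity:
        if sev.label == label:
            return int(sev)
    return 99


def _step_lookup(series: pd.Series, t: float) -> float:
    """Value of a right-continuous step function at time t."""
    idx = series.index.to_numpy(dtype=float)
    vals = series.to_numpy(dtype=float)
    mask = idx <= t
    return float(vals[mask][-1]) if mask.any() else 1.0


def logrank(records: list[SurvivalRecord]) -> tuple[float, int, float]:
    """k-sample log-rank test across severity categories: (chi2, df, p)."""
    cats = {r.category for r in records}
    if len(cats) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records])
    g = np.array([int(r.category) for r in records])
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), len(cats) - 1, float(res.p_value)


def cox_fit(
    df: pd.DataFrame,
    covariate_cols: list[str],
    duration_col: str = "time",
    event_col: str = "event",
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards fit on a numeric design matrix.

    Constant columns are excluded with a warning (their HR is undefined).
    Raises :class:`ConvergenceError` on separation / non-convergence.
    """
    import statsmodels.api as sm

    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    X = df[covariate_cols].astype(float)
    dropped = [c for c in covariate_cols if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"constant covariate(s) excluded from Cox model: {dropped}")
        X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ValueError("no non-constant covariates")
    n_events = int(df[event_col].sum())
    if n_events < X.shape[1]:
        raise ValueError("fewer events than parameters")

    model = sm.PHReg(
        np.asarray(df[duration_col], dtype=float),
        np.asarray(X, dtype=float),
        status=np.asarray(df[event_col], dtype=float),
        ties=ties,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=False)
        except Exception as exc:  # pragma: no cover - backend failure path
            raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    params = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(se))) or np.any(
        np.abs(params) > 50
    ):
        raise ConvergenceError("Cox fit did not converge (possible separation)")
    table = pd.DataFrame(
        {
            "log_hr": params,
            "se": se,
            "hr": np.exp(params),
            "ci_lower": np.exp(params - 1.96 * se),
            "ci_upper": np.exp(params + 1.96 * se),
        },
        index=list(X.columns),
    )
    return CoxResult(
        table=table,
        log_likelihood=float(model.loglike(params)),
        ties=ties,
        n=len(df),
        n_events=n_events,
        dropped=dropped,
    )


def mice_impute(
    frame: pd.DataFrame,
    m: int = 20,
    seed: int = 0,
    n_burn: int = 5,
) -> ImputationSet:
    """Chained-equations multiple imputation of a numeric covariate table.

    Imputation models are fit per column with predictive-mean matching, so
    imputed values are always drawn from observed donors — binary flags stay
    binary and ordinal stages stay on the stage grid.  A table with no
    missing values returns ``m`` identical copies.  Deterministic given
    ``seed``.
    """
    from statsmodels.imputation.mice import MICEData

    if m < 1:
        raise ValueError("m must be >= 1")
    all_missing = [c for c in frame.columns if frame[c].isna().all()]
    if all_missing:
        raise ValueError(f"column(s) with 100% missingness: {all_missing}")
    if not frame.isna().any().any():
        return ImputationSet(completed=[frame.copy() for _ in range(m)], seed=seed)

    work = frame.reset_index(drop=True).astype(float)
    # MICEData draws from the numpy global RandomState; seed it here so the
    # imputation stream is reproducible and isolated per call.
    state = np.random.get_state()
    try:
        np.random.seed(seed % (2**31))
        mdata = MICEData(work)
        completed = []
        for _ in range(m):
            mdata.update_all(n_burn)
            snap = mdata.data.copy()
            snap.index = frame.index
            completed.append(snap)
    finally:
        np.random.set_state(state)
    return ImputationSet(completed=completed, seed=seed)


def pool(results: list[CoxResult]) -> CoxResult:
    """Rubin's-rules pooling of Cox fits across imputed datasets.

    Pooled log-HR is the mean of per-fit log-HRs; total variance is the mean
    within-fit variance plus ``(1 + 1/m)`` times the between-fit variance.
    ``m = 1`` pooling returns the single fit's estimates.
    """
    if not results:
        raise ValueError("nothing to pool")
    m = len(results)
    idx = results[0].table.index
    for r in results[1:]:
        if not r.table.index.equals(idx):
            raise ValueError("covariate sets differ across imputation fits")
    logs = np.array([r.table["log_hr"].to_numpy() for r in results])
    ses = np.array([r.table["se"].to_numpy() for r in results])
    qbar = logs.mean(axis=0)
    within = (ses**2).mean(axis=0)
    between = logs.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    total = within + (1 + 1 / m) * between
    se = np.sqrt(total)
    table = pd.DataFrame(
        {
            "log_hr": qbar,
            "se": se,
            "hr": np.exp(qbar),
            "ci_lower": np.exp(qbar - 1.96 * se),
            "ci_upper": np.exp(qbar + 1.96 * se),
        },
        index=idx,
    )
    return CoxResult(
        table=table,
        log_likelihood=float(np.mean([r.log_likelihood for r in results])),
        ties=results[0].ties,
        n=results[0].n,
        n_events=results[0].n_events,
        dropped=results[0].dropped,
    )


def cox_fit_mice(
    frame: pd.DataFrame,
    covariate_cols: list[str],
    m: int = 20,
    seed: int = 0,
    ties: str = "efron",
) -> CoxResult:
    """Impute missing covariates, fit the Cox model per completed table,
    pool by Rubin's rules.

    ``frame`` is a :func:`records_frame` output; ``time``/``event`` are never
    imputed.
    """
    impute_cols = [c for c in frame.columns if c not in ("time", "event")]
    imputations = mice_impute(frame[impute_cols], m=m, seed=seed)
    fits = []
    for completed in imputations.completed:
        full = completed.copy()
        full["time"] = frame["time"]
        full["event"] = frame["event"]
        design = encode_design(full, covariate_cols)
        design["time"] = full["time"]
        design["event"] = full["event"]
        fits.append(cox_fit(design, [c for c in design.columns if c not in ("time", "event")], ties=ties))
    return pool(fits)


def sensitivity_reruns(
    frame: pd.DataFrame,
    covariate_cols: list[str],
    later_years: tuple[int, int] = (2012, 2017),
    m: int = 20,
    seed: int = 0,
    ties: str = "efron",
) -> dict[str, CoxResult]:
    """Sensitivity analyses: 2012–2017 subset (imputed) and complete-case.

    Raises if the year subset is empty.
    """
    y0, y1 = later_years
    subset = frame[(frame["treatment_year"] >= y0) & (frame["treatment_year"] <= y1)]
    if subset.empty:
        raise ValueError(f"no patients with index year in [{y0}, {y1}]")
    out: dict[str, CoxResult] = {}
    out["later_years"] = cox_fit_mice(subset, covariate_cols, m=m, seed=seed, ties=ties)
    complete = frame.dropna()
    design = encode_design(complete, covariate_cols)
    design["time"] = complete["time"]
    design["event"] = complete["event"]
    out["complete_case"] = cox_fit(
        design, [c for c in design.columns if c not in ("time", "event")], ties=ties
    )
    return out
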