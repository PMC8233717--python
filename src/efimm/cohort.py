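"""Cohort construction: index dates, inclusion/exclusion, attrition.

Selection rules for a newly-treated multiple-myeloma cohort drawn from coded
claims, applied per patient in a fixed order; the first failing rule is the
recorded exclusion reason, and an attrition table reports how many patients
survive each step:

1. at least ``min_mm_dx_dates`` distinct dates bearing an MM diagnosis code
   (ICD-9 prefix 203.0 / ICD-10 prefix C90.0 by default);
2. an index date exists: a first VA treatment (RX) date with a second,
   distinct treatment date within ``treatment_pair_max_days`` (183 days);
3. index year within ``index_year_range`` ([2004, 2017]);
4. age at index >= 65.0 years (exact day counts, 365.25 d/y);
5. VA utilization: >= 1 VA non-MM code in each of the three 365-day blocks
   anchored at the index date;
6. CMS washout: no CMS MM-treatment code before or up to 183 days after the
   index date (evidence of prior/external treatment);
7. positive follow-up: death strictly after the index date.

Rule 7 is a convention of this implementation (survival time must be
positive); everything else is configurable through :class:`CohortCriteria`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .model import CodedEvent, CodeSystem, EventBundle, PatientRecord, Source
from .catalog import normalize_code

__all__ = [
    "CohortCriteria",
    "CohortDecision",
    "AttritionTable",
    "EXCLUSION_ORDER",
    "mm_diagnosis_dates",
    "mm_treatment_dates",
    "determine_index_date",
    "check_utilization",
    "cms_washout",
    "evaluate_patient",
    "build_cohort",
]

DAYS_PER_YEAR_EXACT = 365.25  # age arithmetic only


@dataclass(frozen=True)
class CohortCriteria:
    min_mm_dx_dates: int = 3
    mm_dx_code_prefixes: tuple[tuple[CodeSystem, str], ...] = (
        (CodeSystem.ICD9, "203.0"),
        (CodeSystem.ICD10, "C90.0"),
    )
    treatment_pair_max_days: int = 183
    index_year_range: tuple[int, int] = (2004, 2017)
    age_min_years: float = 65.0
    utilization_years: int = 3
    cms_washout_end_days: int = 183
    require_dx_before_index: bool = False  # "three dates observed", timing unstated
    require_positive_followup: bool = True


# ordered labels; also the attrition steps
EXCLUSION_ORDER = (
    "insufficient_mm_dx_dates",
    "no_index_date",
    "index_year_out_of_range",
    "age_below_minimum",
    "insufficient_va_utilization",
    "cms_washout",
    "nonpositive_followup",
)


@dataclass(frozen=True)
class CohortDecision:
    patient_id: str
    included: bool
    index_date: dt.date | None
    exclusion_reason: str | None

    def __post_init__(self) -> None:
        assert self.included == (self.exclusion_reason is None)
        if self.included:
            assert self.index_date is not None


@dataclass
class AttritionTable:
    """Ordered (criterion label, n remaining) pairs; first row is the input."""

    rows: list[tuple[str, int]] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [{"step": label, "n_remaining": n} for label, n in self.rows]

    @property
    def final_n(self) -> int:
        return self.rows[-1][1]


def _is_mm_dx(event: CodedEvent, criteria: CohortCriteria) -> bool:
    code = normalize_code(event.code)
    return any(
        event.code_system is system and code.startswith(normalize_code(prefix))
        for system, prefix in criteria.mm_dx_code_prefixes
    )


def _is_mm_treatment(event: CodedEvent) -> bool:
    # MM treatment codes are pharmacy (RX) events in this schema
    return event.code_system is CodeSystem.RX


def mm_diagnosis_dates(
    events: list[CodedEvent], criteria: CohortCriteria
) -> list[dt.date]:
    """Sorted distinct dates bearing >= 1 MM diagnosis code."""
    return sorted({e.event_date for e in events if _is_mm_dx(e, criteria)})


def mm_treatment_dates(
    events: list[CodedEvent], source: Source | None = Source.VA
) -> list[dt.date]:
    """Sorted distinct MM treatment dates, optionally restricted by source."""
    return sorted(
        {
            e.event_date
            for e in events
            if _is_mm_treatment(e) and (source is None or e.source is source)
        }
    )


def determine_index_date(
    events: list[CodedEvent], criteria: CohortCriteria
) -> dt.date | None:
    """First VA treatment date, valid only if a second distinct treatment
    date follows within ``treatment_pair_max_days``; else ``None``.

    The second code guards against one-off fills by patients treated
    longitudinally outside the system.
    """
    dates = mm_treatment_dates(events, Source.VA)
    if len(dates) < 2:
        return None
    t1, t2 = dates[0], dates[1]
    gap = (t2 - t1).days
    if 0 < gap <= criteria.treatment_pair_max_days:
        return t1
    return None


def check_utilization(
    events: list[CodedEvent], index_date: dt.date, criteria: CohortCriteria
) -> bool:
    """>= 1 VA non-MM code in each 365-day block before the index date.

    Block k (k = 1..utilization_years) is [index - 365k, index - 365(k-1)).
    MM diagnosis and MM treatment codes do not qualify.
    """
    for k in range(1, criteria.utilization_years + 1):
        lo = index_date - dt.timedelta(days=365 * k)
        hi = index_date - dt.timedelta(days=365 * (k - 1))
        ok = any(
            e.source is Source.VA
            and lo <= e.event_date < hi
            and not _is_mm_dx(e, criteria)
            and not _is_mm_treatment(e)
            for e in events
        )
        if not ok:
            return False
    return True


def cms_washout(
    events: list[CodedEvent], index_date: dt.date, criteria: CohortCriteria
) -> bool:
    """True (= excluded) iff any CMS MM-treatment code is dated on or before
    index + ``cms_washout_end_days``; no lower bound."""
    cutoff = index_date + dt.timedelta(days=criteria.cms_washout_end_days)
    return any(
        e.source is Source.CMS and _is_mm_treatment(e) and e.event_date <= cutoff
        for e in events
    )


def age_at(birth_date: dt.date, on: dt.date) -> float:
    """Age in years from exact day counts (365.25 days/year)."""
    return (on - birth_date).days / DAYS_PER_YEAR_EXACT


def evaluate_patient(
    patient: PatientRecord,
    events: list[CodedEvent],
    criteria: CohortCriteria,
) -> CohortDecision:
    """Apply every criterion in the documented order; first failure wins."""
    dx_dates = mm_diagnosis_dates(events, criteria)
    index_date = determine_index_date(events, criteria)

    def excluded(reason: str) -> CohortDecision:
        return CohortDecision(patient.patient_id, False, None, reason)

    qualifying_dx = dx_dates
    if criteria.require_dx_before_index and index_date is not None:
        qualifying_dx = [d for d in dx_dates if d <= index_date]
    if len(qualifying_dx) < criteria.min_mm_dx_dates:
        return excluded("insufficient_mm_dx_dates")
    if index_date is None:
        return excluded("no_index_date")
    y0, y1 = criteria.index_year_range
    if not (y0 <= index_date.year <= y1):
        return excluded("index_year_out_of_range")
    if age_at(patient.birth_date, index_date) < criteria.age_min_years:
        return excluded("age_below_minimum")
    if not check_utilization(events, index_date, criteria):
        return excluded("insufficient_va_utilization")
    if cms_washout(events, index_date, criteria):
        return excluded("cms_washout")
    if criteria.require_positive_followup and (
        patient.death_date is not None and patient.death_date <= index_date
    ):
        return excluded("nonpositive_followup")
    return CohortDecision(patient.patient_id, True, index_date, None)


def build_cohort(
    bundle: EventBundle, criteria: CohortCriteria | None = None
) -> tuple[list[CohortDecision], AttritionTable]:
    """Evaluate every patient and assemble the attrition table.

    Decisions are returned in patient-id order and are independent of input
    row order (events are grouped and criteria are order-insensitive scans).
    """
    criteria = criteria or CohortCriteria()
    by_patient = bundle.events_by_patient()
    decisions = [
        evaluate_patient(p, by_patient[p.patient_id], criteria)
        for p in sorted(bundle.patients, key=lambda p: p.patient_id)
    ]

    rows: list[tuple[str, int]] = [("all_patients", len(decisions))]
    remaining = len(decisions)
    reason_counts = {r: 0 for r in EXCLUSION_ORDER}
    for d in decisions:
        if d.exclusion_reason is not None:
            reason_counts[d.exclusion_reason] += 1
    for reason in EXCLUSION_ORDER:
        remaining -= reason_counts[reason]
        rows.append((f"after_{reason}", remaining))
    attrition = AttritionTable(rows=rows)
    assert attrition.final_n == sum(1 for d in decisions if d.included)
    return decisions, attrition
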