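"""Baseline covariates: ISS stage, lab-abnormality flags, demographics and
induction-therapy classification.

Labs are taken from a 90-day window closing at the index date, latest value
wins.  ISS staging follows the standard serum albumin / beta-2 microglobulin
rule: stage I if B2M < 3.5 mg/L and albumin >= 3.5 g/dL, stage III if
B2M >= 5.5 mg/L, stage II otherwise; stage III is derivable from B2M alone,
so missing albumin produces a missing stage only when B2M < 3.5.

Induction therapy is read from pharmacy dispense codes in the 90 days after
the index date; "novel therapy" is any proteasome inhibitor (bortezomib,
carfilzomib, ixazomib) or immunomodulatory agent (thalidomide, lenalidomide,
pomalidomide).  Steroids are ignored.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

from .cohort import age_at
from .model import Analyte, CodedEvent, CodeSystem, LabResult, PatientRecord, Race, Sex

__all__ = [
    "BaselineCovariates",
    "NOVEL_AGENTS",
    "latest_lab",
    "derive_iss",
    "lab_flags",
    "induction_therapy",
    "extract_baseline",
]

logger = logging.getLogger(__name__)

LAB_LOOKBACK_DAYS = 90
INDUCTION_WINDOW_DAYS = 90

NOVEL_AGENTS = (
    "thalidomide",
    "lenalidomide",
    "pomalidomide",
    "bortezomib",
    "carfilzomib",
    "ixazomib",
)

# ISS cutoffs from the standard staging definition (external dependency:
# the International Staging System publication, not re-derived here).
ISS_B2M_STAGE1_MAX = 3.5  # mg/L, exclusive
ISS_B2M_STAGE3_MIN = 5.5  # mg/L, inclusive
ISS_ALBUMIN_STAGE1_MIN = 3.5  # g/dL, inclusive


@dataclass(frozen=True)
class BaselineCovariates:
    patient_id: str
    age_at_index: float
    sex: Sex
    race: Race
    income: float | None
    treatment_year: int
    iss_stage: int | None  # 1 | 2 | 3 | None (missing)
    ca_high: bool | None
    cr_high: bool | None
    hgb_low: bool | None
    plt_low: bool | None
    novel_therapy: bool
    agents: frozenset[str]  # subset of NOVEL_AGENTS dispensed at induction


def latest_lab(
    labs: list[LabResult], analyte: Analyte, index_date: dt.date
) -> float | None:
    """Latest value of one analyte in [index - 90 days, index]; None if none.

    Same-date ties resolve by load order (last loaded wins) with a logged
    warning.
    """
    lo = index_date - dt.timedelta(days=LAB_LOOKBACK_DAYS)
    window = [l for l in labs if l.analyte is analyte and lo <= l.date <= index_date]
    if not window:
        return None
    latest_date = max(l.date for l in window)
    on_date = [l for l in window if l.date == latest_date]
    if len(on_date) > 1:
        logger.warning(
            "patient %s: %d %s labs on %s; tie broken by load order",
            on_date[0].patient_id,
            len(on_date),
            analyte.value,
            latest_date,
        )
    return on_date[-1].value


def derive_iss(albumin: float | None, b2m: float | None) -> int | None:
    """International Staging System stage from albumin (g/dL) and B2M (mg/L)."""
    for name, v in (("albumin", albumin), ("beta2_microglobulin", b2m)):
        if v is not None and v < 0:
            raise ValueError(f"negative {name} value {v}")
    if b2m is None:
        return None
    if b2m >= ISS_B2M_STAGE3_MIN:
        return 3
    if b2m < ISS_B2M_STAGE1_MAX:
        if albumin is None:
            return None
        return 1 if albumin >= ISS_ALBUMIN_STAGE1_MIN else 2
    return 2


def lab_flags(
    labs: list[LabResult], index_date: dt.date
) -> dict[str, bool | None]:
    """Tri-state abnormality flags at the printed thresholds.

    calcium >= 11 mg/dL; creatinine > 2 mg/dL; hemoglobin < 10 g/dL;
    platelets < 150 x10^3/uL.  Missing lab -> missing flag.
    """
    ca = latest_lab(labs, Analyte.CALCIUM, index_date)
    cr = latest_lab(labs, Analyte.CREATININE, index_date)
    hgb = latest_lab(labs, Analyte.HEMOGLOBIN, index_date)
    plt = latest_lab(labs, Analyte.PLATELETS, index_date)
    return {
        "ca_high": None if ca is None else ca >= 11.0,
        "cr_high": None if cr is None else cr > 2.0,
        "hgb_low": None if hgb is None else hgb < 10.0,
        "plt_low": None if plt is None else plt < 150.0,
    }


def induction_therapy(
    events: list[CodedEvent], index_date: dt.date
) -> tuple[frozenset[str], bool]:
    """Agents dispensed in [index, index + 90 days] and the novel-therapy flag.

    Pharmacy (RX) codes are matched case-insensitively against the six novel
    agents; any other agent (e.g. melphalan) or steroid contributes nothing.
    """
    hi = index_date + dt.timedelta(days=INDUCTION_WINDOW_DAYS)
    agents = frozenset(
        e.code.lower()
        for e in events
        if e.code_system is CodeSystem.RX
        and index_date <= e.event_date <= hi
        and e.code.lower() in NOVEL_AGENTS
    )
    return agents, bool(agents)


def extract_baseline(
    patient: PatientRecord,
    events: list[CodedEvent],
    labs: list[LabResult],
    index_date: dt.date,
) -> BaselineCovariates:
    """All Table-1-style baseline covariates for one included patient."""
    albumin = latest_lab(labs, Analyte.ALBUMIN, index_date)
    b2m = latest_lab(labs, Analyte.BETA2_MICROGLOBULIN, index_date)
    flags = lab_flags(labs, index_date)
    agents, novel = induction_therapy(events, index_date)
    return BaselineCovariates(
        patient_id=patient.patient_id,
        age_at_index=age_at(patient.birth_date, index_date),
        sex=patient.sex,
        race=patient.race,
        income=patient.income,
        treatment_year=index_date.year,
        iss_stage=derive_iss(albumin, b2m),
        ca_high=flags["ca_high"],
        cr_high=flags["cr_high"],
        hgb_low=flags["hgb_low"],
        plt_low=flags["plt_low"],
        novel_therapy=novel,
        agents=agents,
    )
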