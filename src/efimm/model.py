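"""Core domain types for long-format claims/EHR data.

The whole pipeline consumes one container, :class:`EventBundle`, holding three
linked tables: patient demographics, dated coded events (diagnoses, procedures,
pharmacy dispenses) and laboratory results.  Events carry the payer source
(``VA`` for internal records, ``CMS`` for external Medicare claims), the care
setting, and — for inpatient stays — whether the admission was planned, which
is what the unplanned-hospitalization outcome keys on.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field

__all__ = [
    "Sex",
    "Race",
    "CodeSystem",
    "Source",
    "CareSetting",
    "AdmissionType",
    "PatientRecord",
    "CodedEvent",
    "LabResult",
    "Analyte",
    "EventBundle",
    "ValidationError",
]

DATE_MIN = dt.date(1990, 1, 1)
DATE_MAX = dt.date(2019, 6, 30)


class ValidationError(ValueError):
    """An invariant of the data model was violated."""


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class Race(str, enum.Enum):
    WHITE = "White"
    BLACK = "Black"
    OTHER = "Other"
    MISSING = "Missing"


class CodeSystem(str, enum.Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"
    PROC = "PROC"
    RX = "RX"


class Source(str, enum.Enum):
    VA = "VA"
    CMS = "CMS"


class CareSetting(str, enum.Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"


class AdmissionType(str, enum.Enum):
    PLANNED = "planned"
    UNPLANNED = "unplanned"
    NOT_APPLICABLE = "not_applicable"


class Analyte(str, enum.Enum):
    """Laboratory analytes with fixed units.

    albumin g/dL, beta-2 microglobulin mg/L, calcium mg/dL, creatinine mg/dL,
    hemoglobin g/dL, platelets 10^3/uL.
    """

    ALBUMIN = "albumin"
    BETA2_MICROGLOBULIN = "beta2_microglobulin"
    CALCIUM = "calcium"
    CREATININE = "creatinine"
    HEMOGLOBIN = "hemoglobin"
    PLATELETS = "platelets"


ANALYTE_UNITS = {
    Analyte.ALBUMIN: "g/dL",
    Analyte.BETA2_MICROGLOBULIN: "mg/L",
    Analyte.CALCIUM: "mg/dL",
    Analyte.CREATININE: "mg/dL",
    Analyte.HEMOGLOBIN: "g/dL",
    Analyte.PLATELETS: "10^3/uL",
}


@dataclass(frozen=True)
class PatientRecord:
    """Demographics and vital status for one patient.

    ``income`` is annual income in US dollars; ``None`` encodes the explicit
    "Missing" category.  ``death_date`` is absent for patients alive at their
    last record; ``last_activity_date`` is the last date the patient appears
    in the system and bounds censoring.
    """

    patient_id: str
    birth_date: dt.date
    sex: Sex
    race: Race
    income: float | None
    last_activity_date: dt.date
    death_date: dt.date | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be nonempty")
        if self.death_date is not None and self.birth_date >= self.death_date:
            raise ValidationError(
                f"patient {self.patient_id}: birth_date {self.birth_date} "
                f"not before death_date {self.death_date}"
            )
        if self.last_activity_date < self.birth_date:
            raise ValidationError(
                f"patient {self.patient_id}: last_activity_date precedes birth_date"
            )
        if self.income is not None and self.income < 0:
            raise ValidationError(f"patient {self.patient_id}: negative income")


@dataclass(frozen=True)
class CodedEvent:
    """One dated, coded encounter (diagnosis, procedure or pharmacy code)."""

    patient_id: str
    event_date: dt.date
    code: str
    code_system: CodeSystem
    source: Source
    care_setting: CareSetting
    admission_type: AdmissionType = AdmissionType.NOT_APPLICABLE

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError(f"patient {self.patient_id}: empty code")
        if (
            self.care_setting is not CareSetting.INPATIENT
            and self.admission_type is not AdmissionType.NOT_APPLICABLE
        ):
            raise ValidationError(
                f"patient {self.patient_id}: admission_type="
                f"{self.admission_type.value} requires care_setting=inpatient"
            )
        if not (DATE_MIN <= self.event_date <= DATE_MAX):
            raise ValidationError(
                f"patient {self.patient_id}: event_date {self.event_date} outside "
                f"[{DATE_MIN}, {DATE_MAX}]"
            )

    def sort_key(self) -> tuple:
        # stable chronological order; same-date ties broken deterministically
        return (
            self.event_date,
            self.code_system.value,
            self.code,
            self.source.value,
        )


@dataclass(frozen=True)
class LabResult:
    patient_id: str
    date: dt.date
    analyte: Analyte
    value: float

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(
                f"patient {self.patient_id}: lab value must be finite and >= 0"
            )


@dataclass
class EventBundle:
    """Linked patients + events + labs; the unit of input to every stage.

    Every event and lab ``patient_id`` must resolve to a patient.  Per-patient
    events are retrievable in chronological order with a deterministic
    same-date tie-break via :meth:`events_for`.
    """

    patients: list[PatientRecord] = field(default_factory=list)
    events: list[CodedEvent] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids: {dupes}")
        known = set(ids)
        orphans = sorted(
            {e.patient_id for e in self.events if e.patient_id not in known}
            | {l.patient_id for l in self.labs if l.patient_id not in known}
        )
        if orphans:
            raise ValidationError(
                f"events/labs reference unknown patient ids: {orphans}"
            )

    @property
    def patient_ids(self) -> list[str]:
        return sorted(p.patient_id for p in self.patients)

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def events_for(self, patient_id: str) -> list[CodedEvent]:
        """All events for one patient, chronological, deterministic ties."""
        return sorted(
            (e for e in self.events if e.patient_id == patient_id),
            key=CodedEvent.sort_key,
        )

    def labs_for(self, patient_id: str) -> list[LabResult]:
        return sorted(
            (l for l in self.labs if l.patient_id == patient_id),
            key=lambda l: (l.date, l.analyte.value, l.value),
        )

    def events_by_patient(self) -> dict[str, list[CodedEvent]]:
        """Chronologically sorted events grouped by patient (one pass)."""
        out: dict[str, list[CodedEvent]] = {p.patient_id: [] for p in self.patients}
        for e in self.events:
            out[e.patient_id].append(e)
        for lst in out.values():
            lst.sort(key=CodedEvent.sort_key)
        return out

    def labs_by_patient(self) -> dict[str, list[LabResult]]:
        out: dict[str, list[LabResult]] = {p.patient_id: [] for p in self.patients}
        for l in self.labs:
            out[l.patient_id].append(l)
        for lst in out.values():
            lst.sort(key=lambda l: (l.date, l.analyte.value, l.value))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventBundle):
            return NotImplemented
        return (
            sorted(self.patients, key=lambda p: p.patient_id)
            == sorted(other.patients, key=lambda p: p.patient_id)
            and sorted(self.events, key=CodedEvent.sort_key)
            == sorted(other.events, key=CodedEvent.sort_key)
            and sorted(self.labs, key=lambda l: (l.patient_id, l.date, l.analyte.value, l.value))
            == sorted(other.labs, key=lambda l: (l.patient_id, l.date, l.analyte.value, l.value))
        )
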