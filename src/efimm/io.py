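"""CSV readers/writers for event bundles.

Dialect: UTF-8, comma-delimited, ISO-8601 dates, one table per entity —
``patients.csv``, ``events.csv``, ``labs.csv``.  Missing optional values
(death_date, income) are empty fields, except race/income "Missing" semantics
which are explicit sentinel categories where the schema says so.

Unparseable rows are rejected with their row numbers; nothing is silently
dropped.
"""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path

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
    ValidationError,
)

__all__ = ["read_bundle", "write_bundle", "SchemaError", "BundlePaths", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"

PATIENT_COLUMNS = [
    "patient_id",
    "birth_date",
    "sex",
    "race",
    "income",
    "last_activity_date",
    "death_date",
]
EVENT_COLUMNS = [
    "patient_id",
    "event_date",
    "code",
    "code_system",
    "source",
    "care_setting",
    "admission_type",
]
LAB_COLUMNS = ["patient_id", "date", "analyte", "value"]


class SchemaError(ValueError):
    """Header row does not match the documented schema."""


class BundlePaths:
    """File locations of the three tables; default layout is one directory."""

    def __init__(self, directory: str | Path | None = None, *, patients=None, events=None, labs=None):
        d = Path(directory) if directory is not None else None
        self.patients = Path(patients) if patients else (d / "patients.csv" if d else None)
        self.events = Path(events) if events else (d / "events.csv" if d else None)
        self.labs = Path(labs) if labs else (d / "labs.csv" if d else None)
        if self.patients is None or self.events is None or self.labs is None:
            raise ValueError("BundlePaths needs a directory or all three file paths")


def _parse_date(text: str, *, row: int, table: str, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise ValidationError(f"{table} row {row}: bad date in {column}: {text!r}") from exc


def _parse_enum(enum_cls, text: str, *, row: int, table: str, column: str):
    try:
        return enum_cls(text)
    except ValueError as exc:
        allowed = [m.value for m in enum_cls]
        raise ValidationError(
            f"{table} row {row}: {column}={text!r} not in {allowed}"
        ) from exc


def _check_header(reader: csv.DictReader, expected: list[str], table: str) -> None:
    got = reader.fieldnames or []
    missing = [c for c in expected if c not in got]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}; header was {got}")


def read_bundle(paths: BundlePaths | str | Path, schema_version: str = SCHEMA_VERSION) -> EventBundle:
    """Read and fully link the three CSV tables into an :class:`EventBundle`.

    Raises :class:`SchemaError` for a bad header, :class:`ValidationError`
    (with row numbers) for malformed rows, and a referential-integrity error
    for orphan patient ids.
    """
    if not isinstance(paths, BundlePaths):
        paths = BundlePaths(paths)
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    for p in (paths.patients, paths.events, paths.labs):
        if not p.exists():
            raise FileNotFoundError(p)

    patients: list[PatientRecord] = []
    with open(paths.patients, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, PATIENT_COLUMNS, "patients")
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            income = row["income"].strip()
            death = row["death_date"].strip()
            patients.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    birth_date=_parse_date(row["birth_date"], row=i, table="patients", column="birth_date"),
                    sex=_parse_enum(Sex, row["sex"], row=i, table="patients", column="sex"),
                    race=_parse_enum(Race, row["race"], row=i, table="patients", column="race"),
                    income=float(income) if income else None,
                    last_activity_date=_parse_date(
                        row["last_activity_date"], row=i, table="patients", column="last_activity_date"
                    ),
                    death_date=_parse_date(death, row=i, table="patients", column="death_date")
                    if death
                    else None,
                )
            )

    events: list[CodedEvent] = []
    with open(paths.events, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, EVENT_COLUMNS, "events")
        for i, row in enumerate(reader, start=2):
            try:
                events.append(
                    CodedEvent(
                        patient_id=row["patient_id"],
                        event_date=_parse_date(row["event_date"], row=i, table="events", column="event_date"),
                        code=row["code"],
                        code_system=_parse_enum(CodeSystem, row["code_system"], row=i, table="events", column="code_system"),
                        source=_parse_enum(Source, row["source"], row=i, table="events", column="source"),
                        care_setting=_parse_enum(CareSetting, row["care_setting"], row=i, table="events", column="care_setting"),
                        admission_type=_parse_enum(AdmissionType, row["admission_type"], row=i, table="events", column="admission_type"),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"events row {i}: {exc}") from exc

    labs: list[LabResult] = []
    with open(paths.labs, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, LAB_COLUMNS, "labs")
        for i, row in enumerate(reader, start=2):
            try:
                value = float(row["value"])
            except ValueError as exc:
                raise ValidationError(f"labs row {i}: bad value {row['value']!r}") from exc
            labs.append(
                LabResult(
                    patient_id=row["patient_id"],
                    date=_parse_date(row["date"], row=i, table="labs", column="date"),
                    analyte=_parse_enum(Analyte, row["analyte"], row=i, table="labs", column="analyte"),
                    value=value,
                )
            )

    return EventBundle(patients=patients, events=events, labs=labs)


def _fmt_income(income: float | None) -> str:
    if income is None:
        return ""
    # canonical formatting so a round-trip is bit-equal
    return repr(float(income))


def write_bundle(bundle: EventBundle, paths: BundlePaths | str | Path) -> BundlePaths:
    """Write the three CSV tables; ``read_bundle`` of the result reproduces
    the bundle exactly (canonical row order and value formatting)."""
    if not isinstance(paths, BundlePaths):
        Path(paths).mkdir(parents=True, exist_ok=True)
        paths = BundlePaths(paths)
    bundle.validate()

    with open(paths.patients, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PATIENT_COLUMNS)
        for p in sorted(bundle.patients, key=lambda p: p.patient_id):
            w.writerow(
                [
                    p.patient_id,
                    p.birth_date.isoformat(),
                    p.sex.value,
                    p.race.value,
                    _fmt_income(p.income),
                    p.last_activity_date.isoformat(),
                    p.death_date.isoformat() if p.death_date else "",
                ]
            )

    with open(paths.events, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for e in sorted(bundle.events, key=lambda e: (e.patient_id,) + e.sort_key()):
            w.writerow(
                [
                    e.patient_id,
                    e.event_date.isoformat(),
                    e.code,
                    e.code_system.value,
                    e.source.value,
                    e.care_setting.value,
                    e.admission_type.value,
                ]
            )

    with open(paths.labs, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(LAB_COLUMNS)
        for l in sorted(bundle.labs, key=lambda l: (l.patient_id, l.date, l.analyte.value, l.value)):
            w.writerow([l.patient_id, l.date.isoformat(), l.analyte.value, repr(float(l.value))])

    return paths
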