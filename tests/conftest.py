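"""Shared fixtures: hand-built event-bundle construction helpers and a
small simulated cohort reused across test modules."""

from __future__ import annotations

import datetime as dt

import pytest

from efimm.catalog import default_catalog
from efimm.model import (
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
from efimm.simulate import SimulationConfig, simulate_cohort

D = dt.date


def ev(
    pid: str,
    date: dt.date,
    code: str,
    system: CodeSystem = CodeSystem.ICD10,
    source: Source = Source.VA,
    setting: CareSetting = CareSetting.OUTPATIENT,
    admission: AdmissionType = AdmissionType.NOT_APPLICABLE,
) -> CodedEvent:
    return CodedEvent(
        patient_id=pid,
        event_date=date,
        code=code,
        code_system=system,
        source=source,
        care_setting=setting,
        admission_type=admission,
    )


def patient(
    pid: str,
    birth: dt.date = D(1940, 1, 1),
    death: dt.date | None = D(2014, 1, 1),
    last: dt.date = D(2014, 1, 1),
    sex: Sex = Sex.M,
    race: Race = Race.WHITE,
    income: float | None = 27000.0,
) -> PatientRecord:
    return PatientRecord(
        patient_id=pid,
        birth_date=birth,
        sex=sex,
        race=race,
        income=income,
        last_activity_date=last,
        death_date=death,
    )


def lab(pid: str, date: dt.date, analyte: Analyte, value: float) -> LabResult:
    return LabResult(patient_id=pid, date=date, analyte=analyte, value=value)


def compliant_events(pid: str, index: dt.date = D(2010, 6, 1)) -> list[CodedEvent]:
    """Event stream satisfying every cohort criterion with index `index`:
    3 MM dx dates, treatment pair 11 days apart, one VA non-MM code in each
    lookback year-block, no CMS treatment codes."""
    events = [
        # MM diagnosis on three distinct dates (ICD-9 prefix 203.0)
        ev(pid, index - dt.timedelta(days=140), "203.00", CodeSystem.ICD9),
        ev(pid, index - dt.timedelta(days=110), "203.01", CodeSystem.ICD9),
        ev(pid, index - dt.timedelta(days=80), "203.00", CodeSystem.ICD9),
        # first and second treatment codes, 11 days apart
        ev(pid, index, "lenalidomide", CodeSystem.RX),
        ev(pid, index + dt.timedelta(days=11), "lenalidomide", CodeSystem.RX),
        # VA non-MM utilization, one code per year-block before index
        ev(pid, index - dt.timedelta(days=100), "I10"),
        ev(pid, index - dt.timedelta(days=500), "I10"),
        ev(pid, index - dt.timedelta(days=900), "I10"),
    ]
    return events


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_bundle():
    """Simulated 200-patient bundle + truth, shared read-only."""
    return simulate_cohort(SimulationConfig(n_patients=200, seed=11))


@pytest.fixture()
def six_patient_bundle():
    """Hand-walked fixture: six patients each violating exactly one
    criterion (in evaluation order) plus one fully compliant patient.

    expected exclusion reasons:
      PDX  -> insufficient_mm_dx_dates   (only 2 diagnosis dates)
      PPAIR-> no_index_date              (second treatment 244 d after first)
      PYEAR-> index_year_out_of_range    (index 2002)
      PAGE -> age_below_minimum          (age 64.4 y at index)
      PUTIL-> insufficient_va_utilization(no VA code in year-block 2)
      PWASH-> cms_washout                (CMS treatment code 5 y before index)
      POK  -> included, index 2010-06-01
    """
    index = D(2010, 6, 1)
    patients, events = [], []

    patients.append(patient("PDX"))
    es = compliant_events("PDX", index)
    events += [e for e in es if not (e.code.startswith("203.0") and e.event_date == index - dt.timedelta(days=80))]

    patients.append(patient("PPAIR"))
    es = compliant_events("PPAIR", index)
    es = [e for e in es if e.code_system is not CodeSystem.RX]
    es += [
        ev("PPAIR", index, "lenalidomide", CodeSystem.RX),
        ev("PPAIR", index + dt.timedelta(days=244), "lenalidomide", CodeSystem.RX),
    ]
    events += es

    idx2002 = D(2002, 6, 1)
    patients.append(patient("PYEAR"))
    events += compliant_events("PYEAR", idx2002)

    patients.append(patient("PAGE", birth=D(1946, 1, 1)))
    events += compliant_events("PAGE", index)

    patients.append(patient("PUTIL"))
    es = compliant_events("PUTIL", index)
    events += [e for e in es if not (e.code == "I10" and e.event_date == index - dt.timedelta(days=500))]

    patients.append(patient("PWASH"))
    events += compliant_events("PWASH", index)
    events.append(ev("PWASH", D(2005, 6, 1), "lenalidomide", CodeSystem.RX, source=Source.CMS))

    patients.append(patient("POK"))
    events += compliant_events("POK", index)

    return EventBundle(patients=patients, events=events, labs=[]), index
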