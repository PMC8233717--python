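"""Frailty-index measurement core.

The index is a deficit-accumulation score: scan a patient's coded events in a
lookback window ending at the index date (treatment initiation), mark each
catalog deficit present if at least one qualifying code is found in at least
one of the configured payer sources (a deficit seen in both VA and CMS counts
once), and report the proportion of catalog deficits present,

    F = d / D,   d = #deficits present,  D = catalog size (31 by default),

together with the validated severity categories:

    non-frail        F <= 0.1
    pre-frail        0.1 < F <= 0.2
    mildly frail     0.2 < F <= 0.3
    moderately frail 0.3 < F <= 0.4
    severely frail   F > 0.4

The lookback window is the half-open interval (index - 365*W days, index],
inclusive of the index date — a patient's baseline status at treatment
initiation.  W is 3 years by default, 1 year as a measurement variant.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from .catalog import DeficitCatalog
from .model import CodedEvent, Source

__all__ = [
    "Severity",
    "MeasurementConfig",
    "DeficitProfile",
    "FrailtyScore",
    "ascertain_deficits",
    "compute_fi",
    "classify_severity",
    "score_patient",
    "score_variants",
    "SEVERITY_CUTPOINTS",
]

DAYS_PER_YEAR = 365  # window arithmetic; calendar convention documented

SEVERITY_CUTPOINTS = (0.1, 0.2, 0.3, 0.4)


class Severity(enum.IntEnum):
    """Ordered severity categories; comparisons follow clinical ordering."""

    NON_FRAIL = 0
    PRE_FRAIL = 1
    MILD = 2
    MODERATE = 3
    SEVERE = 4

    @property
    def label(self) -> str:
        return _SEVERITY_LABELS[self]


_SEVERITY_LABELS = {
    Severity.NON_FRAIL: "non-frail",
    Severity.PRE_FRAIL: "pre-frail",
    Severity.MILD: "mildly frail",
    Severity.MODERATE: "moderately frail",
    Severity.SEVERE: "severely frail",
}


@dataclass(frozen=True)
class MeasurementConfig:
    """How the index is measured: lookback length and payer sources.

    The primary specification is a 3-year window over both sources; variants
    drop CMS or shorten the window to 1 year.
    """

    window_years: int = 3
    sources: frozenset[Source] = frozenset({Source.VA, Source.CMS})
    label: str | None = None

    def __post_init__(self) -> None:
        if self.window_years < 1:
            raise ValueError("window_years must be >= 1")
        if not self.sources:
            raise ValueError("sources must be nonempty")
        object.__setattr__(self, "sources", frozenset(self.sources))

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        src = "+".join(sorted(s.value for s in self.sources))
        return f"{src},{self.window_years}y"

    def window(self, index_date: dt.date) -> tuple[dt.date, dt.date]:
        """(open lower bound, inclusive upper bound) of the lookback window."""
        return (
            index_date - dt.timedelta(days=DAYS_PER_YEAR * self.window_years),
            index_date,
        )


@dataclass(frozen=True)
class DeficitProfile:
    """Per-deficit presence indicators with first qualifying dates."""

    patient_id: str
    index_date: dt.date
    present: dict[str, bool]
    first_hit_date: dict[str, dt.date]

    @property
    def present_ids(self) -> frozenset[str]:
        return frozenset(d for d, p in self.present.items() if p)


@dataclass(frozen=True)
class FrailtyScore:
    """Numerator, denominator, exact score and severity category."""

    patient_id: str
    numerator: int
    denominator: int
    category: Severity

    @property
    def score(self) -> float:
        return self.numerator / self.denominator

    @property
    def exact(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)


def classify_severity(score: float) -> Severity:
    """Map a frailty-index value in [0, 1] to its severity category.

    Boundaries are upper-inclusive: F = 0.1 is still non-frail, F = 0.2
    pre-frail, F = 0.3 mildly frail, F = 0.4 moderately frail; anything
    above 0.4 is severely frail.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"frailty score {score} outside [0, 1]")
    c1, c2, c3, c4 = SEVERITY_CUTPOINTS
    if score <= c1:
        return Severity.NON_FRAIL
    if score <= c2:
        return Severity.PRE_FRAIL
    if score <= c3:
        return Severity.MILD
    if score <= c4:
        return Severity.MODERATE
    return Severity.SEVERE


def ascertain_deficits(
    events: Iterable[CodedEvent],
    catalog: DeficitCatalog,
    mconfig: MeasurementConfig,
    index_date: dt.date,
    patient_id: str = "",
) -> DeficitProfile:
    """Mark each catalog deficit present/absent from one patient's events.

    A deficit is present iff at least one event has source in
    ``mconfig.sources``, date in ``(index - 365*W, index]``, and a code
    matching one of the deficit's mappings.  Repeat hits — including hits in
    both sources — count once; the earliest qualifying date is retained.
    """
    lo, hi = mconfig.window(index_date)
    present: dict[str, bool] = {d: False for d in catalog.deficit_ids}
    first_hit: dict[str, dt.date] = {}
    for ev in events:
        patient_id = patient_id or ev.patient_id
        if ev.source not in mconfig.sources:
            continue
        if not (lo < ev.event_date <= hi):
            continue
        for deficit_id in catalog.matching_deficits(ev):
            present[deficit_id] = True
            old = first_hit.get(deficit_id)
            if old is None or ev.event_date < old:
                first_hit[deficit_id] = ev.event_date
    return DeficitProfile(
        patient_id=patient_id,
        index_date=index_date,
        present=present,
        first_hit_date=first_hit,
    )


def compute_fi(profile: DeficitProfile, catalog: DeficitCatalog) -> FrailtyScore:
    """Deficit-proportion score over the catalog's fixed denominator.

    The denominator is the full catalog size regardless of per-patient data
    availability (no eligible-item adjustment).
    """
    d = sum(1 for did in catalog.deficit_ids if profile.present.get(did, False))
    denominator = len(catalog)
    return FrailtyScore(
        patient_id=profile.patient_id,
        numerator=d,
        denominator=denominator,
        category=classify_severity(d / denominator),
    )


def score_patient(
    events: Iterable[CodedEvent],
    catalog: DeficitCatalog,
    mconfig: MeasurementConfig,
    index_date: dt.date,
    patient_id: str = "",
) -> FrailtyScore:
    """Ascertain and score in one call."""
    return compute_fi(
        ascertain_deficits(events, catalog, mconfig, index_date, patient_id=patient_id),
        catalog,
    )


def score_variants(
    events: Sequence[CodedEvent],
    catalog: DeficitCatalog,
    index_date: dt.date,
    variants: Sequence[MeasurementConfig],
) -> dict[str, FrailtyScore]:
    """Score the same event stream under several measurement variants.

    Returns ``{variant.name: FrailtyScore}``; deterministic, and since every
    variant sees the identical stream, nested windows/sources give ordered
    scores (F(1y) <= F(3y); F(VA) <= F(VA+CMS)).
    """
    if not variants:
        raise ValueError("variants must be nonempty")
    events = list(events)
    return {
        mc.name: score_patient(events, catalog, mc, index_date) for mc in variants
    }
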