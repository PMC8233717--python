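"""The deficit catalog: the 31 aging-related health deficits and their code
mappings.

A deficit-accumulation frailty index counts how many items from a fixed
catalog of health deficits a patient exhibits.  The default catalog carries
the standard 31 items grouped into five domains — morbidity (14), function
(8), cognition & mood (3), sensory (3), other (3) — each mapped to diagnosis
or procedure codes via prefix or exact match rules.

The shipped code vocabulary is a *synthetic demo* mapping (one representative
ICD-9-style and ICD-10-style prefix per deficit) sufficient to drive the
simulator and tests; production users load their own validated code lists
with :func:`load_catalog` using the same schema.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import CodedEvent, CodeSystem

__all__ = [
    "Domain",
    "CodeMapping",
    "DeficitItem",
    "DeficitCatalog",
    "CatalogError",
    "default_catalog",
    "load_catalog",
    "normalize_code",
]


class CatalogError(ValueError):
    """Catalog file or definition violates the catalog schema."""


class Domain(str, enum.Enum):
    MORBIDITY = "morbidity"
    FUNCTION = "function"
    COGNITION_MOOD = "cognition_mood"
    SENSORY = "sensory"
    OTHER = "other"


def normalize_code(code: str) -> str:
    """Canonical code form: dots removed, upper-cased.

    ICD prefix semantics survive normalization ("C90.01" -> "C9001" still
    starts with "C900"); matching is robust to dotted/undotted dialects.
    """
    return code.replace(".", "").upper()


@dataclass(frozen=True)
class CodeMapping:
    code_system: CodeSystem
    match_rule: str  # "prefix" | "exact"
    pattern: str

    def __post_init__(self) -> None:
        if self.match_rule not in ("prefix", "exact"):
            raise CatalogError(f"unknown match_rule {self.match_rule!r}")
        if not self.pattern:
            raise CatalogError("empty pattern")

    def matches(self, event: CodedEvent) -> bool:
        if event.code_system is not self.code_system:
            return False
        code = normalize_code(event.code)
        pat = normalize_code(self.pattern)
        return code.startswith(pat) if self.match_rule == "prefix" else code == pat


@dataclass(frozen=True)
class DeficitItem:
    deficit_id: str
    name: str
    domain: Domain
    mappings: tuple[CodeMapping, ...]

    def __post_init__(self) -> None:
        if not self.mappings:
            raise CatalogError(f"deficit {self.deficit_id!r} has no code mappings")


@dataclass
class DeficitCatalog:
    """An ordered collection of deficits; order fixes report-table layout."""

    items: list[DeficitItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.deficit_id for d in self.items]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogError(f"duplicate deficit ids: {dupes}")
        for item in self.items:
            if not isinstance(item.domain, Domain):
                raise CatalogError(f"unknown domain for deficit {item.deficit_id!r}")
        if len(self.items) != 31:
            warnings.warn(
                f"nonstandard denominator: catalog has {len(self.items)} items "
                "(standard index uses 31); severity cut-points are unchanged",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.items)

    @property
    def deficit_ids(self) -> list[str]:
        return [d.deficit_id for d in self.items]

    def item(self, deficit_id: str) -> DeficitItem:
        for d in self.items:
            if d.deficit_id == deficit_id:
                return d
        raise KeyError(deficit_id)

    def domain_counts(self) -> dict[Domain, int]:
        counts = {d: 0 for d in Domain}
        for item in self.items:
            counts[item.domain] += 1
        return counts

    def matching_deficits(self, event: CodedEvent) -> list[str]:
        """Deficit ids whose mappings match one event (brute scan)."""
        return [
            d.deficit_id
            for d in self.items
            if any(m.matches(event) for m in d.mappings)
        ]


def _item(deficit_id: str, name: str, domain: Domain, icd9: str, icd10: str) -> DeficitItem:
    return DeficitItem(
        deficit_id=deficit_id,
        name=name,
        domain=domain,
        mappings=(
            CodeMapping(CodeSystem.ICD9, "prefix", icd9),
            CodeMapping(CodeSystem.ICD10, "prefix", icd10),
        ),
    )


# Demo vocabulary: one representative ICD-9 / ICD-10 prefix per deficit.
# Synthetic stand-in for a validated production code list; see module docstring.
_DEFAULT_ITEMS: list[tuple[str, str, Domain, str, str]] = [
    # morbidity (14)
    ("atrial_fibrillation", "Atrial Fibrillation", Domain.MORBIDITY, "427.3", "I48"),
    ("anemia", "Anemia", Domain.MORBIDITY, "285", "D64"),
    ("cad", "Coronary Artery Disease", Domain.MORBIDITY, "414", "I25"),
    ("cancer", "Cancer", Domain.MORBIDITY, "203", "C90"),
    ("cvd", "Cerebral Vascular Disease", Domain.MORBIDITY, "434", "I63"),
    ("ckd", "Chronic Kidney Disease", Domain.MORBIDITY, "585", "N18"),
    ("diabetes", "Diabetes", Domain.MORBIDITY, "250", "E11"),
    ("heart_failure", "Heart Failure", Domain.MORBIDITY, "428", "I50"),
    ("hypertension", "Hypertension", Domain.MORBIDITY, "401", "I10"),
    ("liver_disease", "Liver Disease", Domain.MORBIDITY, "571", "K70"),
    ("lung_disease", "Lung Disease", Domain.MORBIDITY, "496", "J44"),
    ("thyroid_disease", "Thyroid Disease", Domain.MORBIDITY, "244", "E03"),
    ("osteoporosis", "Osteoporosis or Osteoporosis-Related Fracture", Domain.MORBIDITY, "733.0", "M81"),
    ("incontinence", "Incontinence", Domain.MORBIDITY, "788.3", "R32"),
    # function (8)
    ("arthritis", "Arthritis", Domain.FUNCTION, "715", "M19"),
    ("dme", "Durable Medical Equipment", Domain.FUNCTION, "V53.8", "Z46.8"),
    ("falls", "Falls", Domain.FUNCTION, "E888", "W19"),
    ("fatigue", "Fatigue", Domain.FUNCTION, "780.7", "R53"),
    ("gait_abnormality", "Gait Abnormality", Domain.FUNCTION, "781.2", "R26"),
    ("muscular_impairment", "Muscular impairment/Debility", Domain.FUNCTION, "728.8", "M62.8"),
    ("parkinsons", "Parkinson's Disease", Domain.FUNCTION, "332", "G20"),
    ("pvd", "Peripheral Vascular Disease/Claudication", Domain.FUNCTION, "443", "I73"),
    # cognition & mood (3)
    ("dementia", "Dementia", Domain.COGNITION_MOOD, "290", "F03"),
    ("anxiety", "Anxiety", Domain.COGNITION_MOOD, "300.0", "F41"),
    ("depression", "Depression", Domain.COGNITION_MOOD, "311", "F32"),
    # sensory (3)
    ("peripheral_neuropathy", "Peripheral Neuropathy", Domain.SENSORY, "356", "G62"),
    ("hearing_impairment", "Hearing Impairment", Domain.SENSORY, "389", "H91"),
    ("vision_impairment", "Vision Impairment", Domain.SENSORY, "369", "H54"),
    # other (3)
    ("chronic_pain", "Chronic Pain", Domain.OTHER, "338", "G89"),
    ("failure_to_thrive", "Failure to Thrive", Domain.OTHER, "783.7", "R62.7"),
    ("weight_loss", "Weight Loss", Domain.OTHER, "783.2", "R63.4"),
]


def default_catalog() -> DeficitCatalog:
    """The shipped 31-item catalog (demo vocabulary)."""
    return DeficitCatalog(items=[_item(*row) for row in _DEFAULT_ITEMS])


def load_catalog(path: str | Path) -> DeficitCatalog:
    """Load a catalog from CSV (one row per mapping) or YAML.

    CSV columns: deficit_id, name, domain, code_system, match_rule, pattern.
    YAML: a list of ``{deficit_id, name, domain, mappings: [{code_system,
    match_rule, pattern}]}``.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        items = []
        for entry in raw:
            items.append(
                DeficitItem(
                    deficit_id=entry["deficit_id"],
                    name=entry.get("name", entry["deficit_id"]),
                    domain=_parse_domain(entry["domain"]),
                    mappings=tuple(
                        CodeMapping(CodeSystem(m["code_system"]), m["match_rule"], m["pattern"])
                        for m in entry.get("mappings", [])
                    ),
                )
            )
        return DeficitCatalog(items=items)

    grouped: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"deficit_id", "name", "domain", "code_system", "match_rule", "pattern"}
        if not required.issubset(reader.fieldnames or []):
            raise CatalogError(
                f"catalog CSV missing columns {sorted(required - set(reader.fieldnames or []))}"
            )
        for row in reader:
            did = row["deficit_id"]
            if did not in grouped:
                grouped[did] = {"name": row["name"], "domain": row["domain"], "mappings": []}
                order.append(did)
            grouped[did]["mappings"].append(
                CodeMapping(CodeSystem(row["code_system"]), row["match_rule"], row["pattern"])
            )
    items = [
        DeficitItem(
            deficit_id=did,
            name=grouped[did]["name"],
            domain=_parse_domain(grouped[did]["domain"]),
            mappings=tuple(grouped[did]["mappings"]),
        )
        for did in order
    ]
    return DeficitCatalog(items=items)


def _parse_domain(text: str) -> Domain:
    try:
        return Domain(text)
    except ValueError as exc:
        raise CatalogError(f"unknown domain {text!r}") from exc


def save_catalog(catalog: DeficitCatalog, path: str | Path) -> None:
    """Write a catalog as the CSV schema accepted by :func:`load_catalog`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["deficit_id", "name", "domain", "code_system", "match_rule", "pattern"])
        for item in catalog.items:
            for m in item.mappings:
                w.writerow(
                    [item.deficit_id, item.name, item.domain.value, m.code_system.value, m.match_rule, m.pattern]
                )
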