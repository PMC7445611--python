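"""Mapping between report elements and FHIR STU3 Genomics resources.

Each row of the table is one *mapped FHIR element slot*: a target resource
type, the path expression in the source dialect (``extension(name)`` for
extension slots, ``subject(patient)`` for a reference dereference), whether
the slot reuses a core FHIR element or defines an extension, and a parsed
structural placement used by the bundle builder and coverage audit.

A single report element may occupy more than one slot (the variant
classification expands into three sub-extensions; subject demographics
appear both via the report's patient dereference and on the Patient
resource itself), which is how 61 registry elements yield 90 mapped slots:
41 for the required fields (26 reused + 15 extended) and 49 for the
optional fields (28 reused + 21 extended).
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Literal

from pydantic import BaseModel, ConfigDict

from .errors import NotFoundError, RegistryError
from .iso_schema import element_lookup, load_element_registry

__all__ = [
    "EXTENSION_BASE_URL",
    "FhirTarget",
    "MappingRow",
    "ExtensionDef",
    "MappingStatistics",
    "load_mapping_table",
    "map_element",
    "rows_for_element",
    "mapping_statistics",
    "extension_definitions",
    "export_mapping_csv",
    "import_mapping_csv",
    "export_mapping_json",
]

EXTENSION_BASE_URL = "https://seqreport.example.org/fhir/StructureDefinition/"

ResourceType = Literal[
    "ProcedureRequest", "DiagnosticReport", "Observation", "Medication",
    "Patient", "Condition", "MolecularSequence", "Device",
]
RESOURCE_TYPES = (
    "ProcedureRequest", "DiagnosticReport", "Observation", "Medication",
    "Patient", "Condition", "MolecularSequence", "Device",
)

#: accepted aliases on input (the request profile was renamed upstream)
RESOURCE_ALIASES = {"ServiceRequest": "ProcedureRequest", "Sequence": "MolecularSequence"}

CSV_COLUMNS = ("element_id", "field_class", "resource_type", "fhir_path",
               "mapping_kind", "extension_url")


class FhirTarget(BaseModel):
    """Where one element slot lands in FHIR."""

    model_config = ConfigDict(frozen=True)

    resource_type: ResourceType
    fhir_path: str
    mapping_kind: Literal["reuse", "extension"]
    extension_url: str = ""


class MappingRow(BaseModel):
    """One mapped element slot with its machine placement."""

    model_config = ConfigDict(frozen=True)

    element_id: str
    field_class: Literal["required", "optional"]
    target: FhirTarget
    #: slash-separated structural path: keys, list indices, ``ext:NAME``
    #: extension steps, ``@Patient`` reference dereference and
    #: ``component{code}`` component selection.
    placement: str


class ExtensionDef(BaseModel):
    """A named, URL-identified extension and its semantic datatype."""

    model_config = ConfigDict(frozen=True)

    url: str
    name: str
    value_type: Literal["string", "code", "codeable-concept", "identifier",
                        "quantity", "reference"]
    host_resource: ResourceType


@dataclass(frozen=True)
class MappingStatistics:
    """Per-resource (reused element, extension) slot counts by field class."""

    required: dict[str, tuple[int, int]]
    optional: dict[str, tuple[int, int]]

    @property
    def required_total(self) -> tuple[int, int]:
        return (sum(v[0] for v in self.required.values()),
                sum(v[1] for v in self.required.values()))

    @property
    def optional_total(self) -> tuple[int, int]:
        return (sum(v[0] for v in self.optional.values()),
                sum(v[1] for v in self.optional.values()))

    @property
    def grand_total(self) -> int:
        r, o = self.required_total, self.optional_total
        return r[0] + r[1] + o[0] + o[1]


def _sort_key(r: MappingRow):
    return (r.field_class, r.target.resource_type, r.element_id, r.target.fhir_path)


@lru_cache(maxsize=None)
def load_mapping_table() -> tuple[MappingRow, ...]:
    """Load and sanity-check the embedded mapping table."""
    raw = json.loads(
        resources.files("seqreport.data").joinpath("mapping.json").read_text("utf-8")
    )
    rows = tuple(
        MappingRow(
            element_id=r["element_id"],
            field_class=r["field_class"],
            target=FhirTarget(
                resource_type=r["resource_type"],
                fhir_path=r["fhir_path"],
                mapping_kind=r["mapping_kind"],
                extension_url=r["extension_url"],
            ),
            placement=r["placement"],
        )
        for r in raw
    )
    registry_ids = {s.element_id for s in load_element_registry()}
    for r in rows:
        if r.element_id not in registry_ids:
            raise RegistryError(f"mapping references unknown element {r.element_id!r}")
        t = r.target
        is_ext = t.mapping_kind == "extension"
        if is_ext != ("extension(" in t.fhir_path) or is_ext != bool(t.extension_url):
            raise RegistryError(f"inconsistent extension marking on {r.element_id!r}")
        if element_lookup(r.element_id).field_class != r.field_class:
            raise RegistryError(f"field-class mismatch for {r.element_id!r}")
    if len(rows) != 90:
        raise RegistryError(f"mapping table has {len(rows)} slots (expected 90)")
    return rows


def rows_for_element(element_id: str) -> tuple[MappingRow, ...]:
    """All slots an element occupies (may be more than one)."""
    element_lookup(element_id)  # raises NotFoundError with suggestions
    return tuple(r for r in load_mapping_table() if r.element_id == element_id)


def map_element(element_id: str) -> FhirTarget:
    """Return the primary FHIR target of a registry element.

    The primary slot is the first mapping row for the element in table
    order, which for every element is the slot on its home resource.
    """
    return rows_for_element(element_id)[0].target


def mapping_statistics(rows: Iterable[MappingRow] | None = None) -> MappingStatistics:
    """Count (reused, extension) slots per field class and resource type."""
    rows = load_mapping_table() if rows is None else tuple(rows)
    counts: dict[str, dict[str, list[int]]] = {"required": {}, "optional": {}}
    for r in rows:
        pair = counts[r.field_class].setdefault(r.target.resource_type, [0, 0])
        pair[0 if r.target.mapping_kind == "reuse" else 1] += 1
    return MappingStatistics(
        required={k: tuple(v) for k, v in counts["required"].items()},
        optional={k: tuple(v) for k, v in counts["optional"].items()},
    )


@lru_cache(maxsize=None)
def extension_definitions() -> tuple[ExtensionDef, ...]:
    """All registered extension definitions (unique URLs)."""
    raw = json.loads(
        resources.files("seqreport.data").joinpath("extensions.json").read_text("utf-8")
    )
    defs = tuple(ExtensionDef(**d) for d in raw)
    urls = [d.url for d in defs]
    if len(urls) != len(set(urls)):
        raise RegistryError("duplicate extension URLs in registry")
    known = set(urls)
    for r in load_mapping_table():
        if r.target.mapping_kind == "extension" and r.target.extension_url not in known:
            raise RegistryError(f"unregistered extension {r.target.extension_url!r}")
    return defs


def extension_by_name(name: str) -> ExtensionDef:
    for d in extension_definitions():
        if d.name == name:
            return d
    raise NotFoundError(f"unknown extension {name!r}")


def structure_definition_stub(defn: ExtensionDef) -> dict:
    """A minimal conformance-resource stub for one extension."""
    return {
        "resourceType": "StructureDefinition",
        "url": defn.url,
        "name": defn.name,
        "kind": "complex-type",
        "type": "Extension",
        "context": [defn.host_resource],
        "valueType": defn.value_type,
    }


# ------------------------------------------------------------------ I/O

def export_mapping_csv(rows: Iterable[MappingRow] | None = None) -> str:
    """Serialize the mapping table to CSV with byte-stable ordering."""
    rows = load_mapping_table() if rows is None else tuple(rows)
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(CSV_COLUMNS)
    for r in sorted(rows, key=_sort_key):
        t = r.target
        w.writerow([r.element_id, r.field_class, t.resource_type, t.fhir_path,
                    t.mapping_kind, t.extension_url])
    return buf.getvalue()


def import_mapping_csv(text: str) -> tuple[MappingRow, ...]:
    """Parse a CSV produced by :func:`export_mapping_csv` (lossless)."""
    reader = csv.DictReader(io.StringIO(text))
    placements = {
        (r.element_id, r.target.resource_type, r.target.fhir_path): r.placement
        for r in load_mapping_table()
    }
    out = []
    for rec in reader:
        rtype = RESOURCE_ALIASES.get(rec["resource_type"], rec["resource_type"])
        out.append(MappingRow(
            element_id=rec["element_id"],
            field_class=rec["field_class"],
            target=FhirTarget(
                resource_type=rtype,
                fhir_path=rec["fhir_path"],
                mapping_kind=rec["mapping_kind"],
                extension_url=rec["extension_url"],
            ),
            placement=placements.get((rec["element_id"], rtype, rec["fhir_path"]), ""),
        ))
    return tuple(out)


def export_mapping_json(rows: Iterable[MappingRow] | None = None) -> str:
    rows = load_mapping_table() if rows is None else tuple(rows)
    payload = [
        {
            "element_id": r.element_id,
            "field_class": r.field_class,
            "resource_type": r.target.resource_type,
            "fhir_path": r.target.fhir_path,
            "mapping_kind": r.target.mapping_kind,
            "extension_url": r.target.extension_url,
        }
        for r in sorted(rows, key=_sort_key)
    ]
    return json.dumps(payload, indent=1) + "\n"
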