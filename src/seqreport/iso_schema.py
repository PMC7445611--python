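"""Element registry for the structured clinical sequencing report.

The report template distinguishes *required* data elements (the clinically
actionable core: subject of care, sequencing order, biomaterial, genetic
variation, recommended treatments) from *optional* elements aimed at
clinical research (alignment coordinates, quality-control and pipeline
metadata).  Each element carries a metadata/terminology binding — the
standard that governs how its value is written (HGNC for gene names, HGVS
for variant notation, ISO 8601 for dates, the subject-identification
standard for demographics, an HL7 v3 code system for race/ethnicity).

The registry ships with the package as JSON data.  Elements whose identity
is directly attested by the source report template are flagged
``provenance="paper"``; elements whose names had to be reconstructed (the
full normative element list is not freely redistributable) are flagged
``provenance="reconstructed"`` — their count and section placement are
constrained so that every published cardinality holds.
"""

from __future__ import annotations

import difflib
import json
from functools import lru_cache
from importlib import resources
from typing import Literal

from pydantic import BaseModel, ConfigDict

from .errors import NotFoundError, RegistryError

__all__ = [
    "ElementSpec",
    "ValueSet",
    "load_element_registry",
    "element_lookup",
    "value_set",
    "value_set_names",
    "SEX_CODE_TO_GENDER",
    "GENDER_TO_SEX_CODE",
]

MetadataStandard = Literal[
    "ISO/TS 22220:2011", "ISO 8601", "HL7 v3 race", "HGNC", "HGVS",
    "database-ID", "text", "none",
]


class ElementSpec(BaseModel):
    """One data element of the structured report template."""

    model_config = ConfigDict(frozen=True)

    element_id: str
    display_name: str
    field_class: Literal["required", "optional"]
    section: str
    metadata_standard: MetadataStandard
    provenance: Literal["paper", "reconstructed"]


class ValueSet(BaseModel):
    """An ordered, immutable list of (code, display) pairs."""

    model_config = ConfigDict(frozen=True)

    name: str
    codes: tuple[tuple[str, str], ...]

    def __contains__(self, code: object) -> bool:
        return any(c == code for c, _ in self.codes)

    def display(self, code: str) -> str:
        for c, d in self.codes:
            if c == code:
                return d
        raise NotFoundError(f"code {code!r} not in value set {self.name!r}")


# Subject sex uses the numeric coding of the subject-identification standard
# ("1" = Male is fixed by the template example; the rest follow the common
# 0/1/2/9 convention).  The FHIR-side gender token is a translation of it.
SEX_CODE_TO_GENDER = {"0": "unknown", "1": "male", "2": "female", "9": "other"}
GENDER_TO_SEX_CODE = {v: k for k, v in SEX_CODE_TO_GENDER.items()}


def _data_text(name: str) -> str:
    return resources.files("seqreport.data").joinpath(name).read_text("utf-8")


@lru_cache(maxsize=None)
def _registry() -> tuple[ElementSpec, ...]:
    raw = json.loads(_data_text("elements.json"))
    specs = tuple(ElementSpec(**row) for row in raw)
    seen: set[str] = set()
    for s in specs:
        if s.element_id in seen:
            raise RegistryError(f"duplicate element id in registry: {s.element_id!r}")
        seen.add(s.element_id)
    n_req = sum(1 for s in specs if s.field_class == "required")
    n_opt = len(specs) - n_req
    if (n_req, n_opt) != (32, 29):
        raise RegistryError(
            f"registry cardinality corrupt: {n_req} required / {n_opt} optional "
            "(expected 32 / 29)"
        )
    return specs


def load_element_registry() -> tuple[ElementSpec, ...]:
    """Return the full element registry (stable order, idempotent)."""
    return _registry()


def element_lookup(element_id: str) -> ElementSpec:
    """Return the spec for *element_id*, or raise with nearest matches."""
    for s in _registry():
        if s.element_id == element_id:
            return s
    near = difflib.get_close_matches(element_id, [s.element_id for s in _registry()], n=3)
    hint = f"; nearest: {', '.join(near)}" if near else ""
    raise NotFoundError(f"unknown element id {element_id!r}{hint}")


@lru_cache(maxsize=None)
def _value_sets() -> dict[str, ValueSet]:
    raw = json.loads(_data_text("value_sets.json"))
    return {
        name: ValueSet(name=name, codes=tuple((c, d) for c, d in pairs))
        for name, pairs in raw.items()
    }


def value_set(name: str) -> ValueSet:
    """Return a registered value set by name."""
    try:
        return _value_sets()[name]
    except KeyError:
        raise NotFoundError(
            f"unknown value set {name!r}; registered: {', '.join(sorted(_value_sets()))}"
        ) from None


def value_set_names() -> tuple[str, ...]:
    return tuple(_value_sets())
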