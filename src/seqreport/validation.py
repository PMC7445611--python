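"""Conformance checking against the element registry and value sets.

Required-field completeness is the gate the bundle builder applies: a
report validates cleanly iff :func:`validate_report` returns no
error-severity issue.  Optional-field absence is never an issue; problems
on optional fields are warnings.  Terminology checks are lexical and
offline — the race code system ships as a bundled micro-valueset, HGNC ids
are pattern-checked, dates must parse as ISO 8601.
"""

from __future__ import annotations

import datetime as _dt
import re
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from .errors import NotFoundError
from .fhir_model import Bundle, walk_placement
from .iso_schema import load_element_registry, value_set
from .mapping import MappingStatistics, load_mapping_table
from .report_builder import (
    HGNC_ID_RE,
    SequencingReport,
    VARIANT_GETTERS,
    element_value,
)

__all__ = ["ValidationIssue", "validate_report", "validate_code", "coverage_summary"]

RACE_CODE_RE = re.compile(r"^\d+-\d$")

#: suggested (not binding) phrasings for the free-text variant effect field
VARIANT_EFFECT_SUGGESTIONS = (
    "Substitution (missense)", "Substitution (nonsense)", "Substitution (silent)",
    "Deletion (in-frame)", "Deletion (frameshift)", "Insertion (in-frame)",
    "Insertion (frameshift)", "Duplication", "Splice-site variant",
)

_ISO_DATE_ELEMENTS = {
    "subject.birth_date", "order.order_date", "specimen.collection_date",
    "report.issued_date", "genetic_variation.observation_date",
}

_NUMERIC_OPTIONAL = {
    "research.window_start", "research.window_end", "research.variant_start",
    "research.variant_end", "research.quality_score", "research.read_coverage",
    "research.coordinate_system", "research.mean_target_depth",
    "research.percent_target_covered", "research.duplication_rate",
    "research.allele_frequency",
}


class ValidationIssue(BaseModel):
    model_config = ConfigDict(frozen=True)

    severity: Literal["error", "warning"]
    element_id: str
    code: Literal["missing-required", "bad-code", "bad-format", "unmapped"]
    message: str


def _iso_date_ok(text: str) -> bool:
    for parse in (_dt.date.fromisoformat, _dt.datetime.fromisoformat):
        try:
            parse(text)
            return True
        except ValueError:
            continue
    return False


def validate_code(system: str, code: str) -> Optional[ValidationIssue]:
    """Lexical/value-set check of one code; None means the code conforms."""
    def bad(kind, msg):
        return ValidationIssue(severity="error", element_id=system, code=kind,
                               message=msg)

    if system == "HGNC":
        return None if HGNC_ID_RE.match(code) else \
            bad("bad-format", f"{code!r} does not match 'HGNC:<digits>'")
    if system == "ISO 8601":
        return None if _iso_date_ok(code) else \
            bad("bad-format", f"{code!r} is not an ISO 8601 date")
    if system == "HL7 v3 race":
        return None if RACE_CODE_RE.match(code) else \
            bad("bad-format", f"{code!r} does not match the '<digits>-<digit>' shape")
    if system == "ISO/TS 22220:2011":
        return None if code in value_set("sex_iso22220") else \
            bad("bad-code", f"sex code {code!r} not in value set sex_iso22220")
    try:
        vs = value_set(system)
    except NotFoundError:
        raise NotFoundError(f"unknown code system {system!r}") from None
    return None if code in vs else \
        bad("bad-code", f"code {code!r} not in value set {system!r}")


def validate_report(report: SequencingReport) -> list[ValidationIssue]:
    """All conformance findings for a report; empty list iff conformant."""
    issues: list[ValidationIssue] = []

    def add(severity, eid, code, msg):
        issues.append(ValidationIssue(severity=severity, element_id=eid,
                                      code=code, message=msg))

    registry = load_element_registry()
    for spec in registry:
        eid = spec.element_id
        if spec.field_class != "required":
            continue
        if eid in VARIANT_GETTERS:
            if not report.variants:
                if not report.no_variants_reported:
                    add("error", eid, "missing-required",
                        f"required element {eid!r} is absent (no variants reported)")
                continue
            missing = [i for i, v in enumerate(report.variants)
                       if element_value(report, eid, v) is None]
            if missing:
                add("error", eid, "missing-required",
                    f"required element {eid!r} absent on variant(s) "
                    + ", ".join(map(str, missing)))
        else:
            if element_value(report, eid) is None:
                add("error", eid, "missing-required",
                    f"required element {eid!r} is not populated")

    # format / code checks on populated fields
    subj = report.subject
    if subj is not None:
        if subj.sex_code is not None and subj.sex_code not in value_set("sex_iso22220"):
            add("error", "subject.sex", "bad-code",
                f"sex code {subj.sex_code!r} not in value set sex_iso22220")
        if subj.ethnicity_code is not None and not RACE_CODE_RE.match(subj.ethnicity_code):
            add("error", "subject.ethnicity", "bad-format",
                f"race code {subj.ethnicity_code!r} has the wrong lexical shape")
    for eid in _ISO_DATE_ELEMENTS - set(VARIANT_GETTERS):
        val = element_value(report, eid)
        if val is not None and not _iso_date_ok(val):
            add("error", eid, "bad-format", f"{eid}: {val!r} is not ISO 8601")
    for i, v in enumerate(report.variants):
        if v.observation_date is not None and not _iso_date_ok(v.observation_date):
            add("error", "genetic_variation.observation_date", "bad-format",
                f"variant {i}: {v.observation_date!r} is not ISO 8601")
        if v.variant_effect is not None and v.variant_effect not in VARIANT_EFFECT_SUGGESTIONS:
            add("warning", "genetic_variation.variant_effect", "bad-code",
                f"variant {i}: effect {v.variant_effect!r} is free text; "
                "suggested phrasings include "
                + ", ".join(repr(s) for s in VARIANT_EFFECT_SUGGESTIONS[:3]) + ", ...")

    known_ids = {s.element_id for s in registry}
    for key, val in report.research.items():
        if key not in known_ids:
            add("warning", key, "unmapped",
                f"research key {key!r} is not a registry element")
        elif key in _NUMERIC_OPTIONAL and not isinstance(val, (int, float)):
            add("warning", key, "bad-format", f"{key} should be numeric, got {val!r}")
    return issues


def coverage_summary(bundle: Bundle) -> MappingStatistics:
    """Count mapped slots actually populated in a bundle, Table-2 shaped."""
    by_type: dict[str, list] = {}
    for e in bundle.entries:
        by_type.setdefault(e.resource_type, []).append(e)
    counts: dict[str, dict[str, list[int]]] = {"required": {}, "optional": {}}
    for row in load_mapping_table():
        candidates = by_type.get(row.target.resource_type, [])
        present = any(
            walk_placement(bundle, res, row.placement) is not None
            for res in candidates
        )
        pair = counts[row.field_class].setdefault(row.target.resource_type, [0, 0])
        if present:
            pair[0 if row.target.mapping_kind == "reuse" else 1] += 1
    return MappingStatistics(
        required={k: tuple(v) for k, v in counts["required"].items()},
        optional={k: tuple(v) for k, v in counts["optional"].items()},
    )
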