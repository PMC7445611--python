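"""Sequencing-report document model, composite grammars and bundle round-trip.

A :class:`SequencingReport` is the structured clinical report: subject
demographics, order and performer metadata, biomaterial, one record per
reported variant, recommended treatments, and an optional research block
keyed by optional element ids.  :func:`build_bundle` places every populated
element at the FHIR slot the mapping table assigns to it and returns a
collection Bundle; :func:`extract_report` inverts the builder on its image.

Two composite-field grammars from the source template are handled here:

* the pathological tier string ``"Tier 1 (Pathogenic, Identified)"`` which
  decomposes into a (tier, pathogenicity, clinical relevance) triple, and
* the variant-notation dialect ``"c.1799T > A_p.V600E"`` — a cDNA HGVS
  change and an optional protein change joined by an underscore, with
  spaces allowed around ``>``.  The raw string is preserved verbatim for
  display; the normalized HGVS forms are stored alongside.
"""

from __future__ import annotations

import copy
import json
import re
from typing import Any, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import BuildError, ExtractionError, GrammarError
from .fhir_model import Bundle, FhirResource, make_resource, set_placement, walk_placement
from .iso_schema import SEX_CODE_TO_GENDER, load_element_registry, value_set
from .mapping import (
    MappingRow,
    extension_definitions,
    load_mapping_table,
)

__all__ = [
    "SubjectInfo", "OrderInfo", "SpecimenInfo", "ReportMeta",
    "ClassificationTriple", "VariantRecord", "SequencingReport",
    "parse_classification", "format_classification", "parse_variant_notation",
    "build_bundle", "extract_report", "extract_report_detailed",
    "report_to_dict", "report_from_dict", "report_from_text",
]

HGNC_ID_RE = re.compile(r"^HGNC:\d+$")
GENE_SYSTEM = "http://www.genenames.org"


# ------------------------------------------------------------- documents

class SubjectInfo(BaseModel):
    model_config = ConfigDict(validate_assignment=True)

    identifier: Optional[str] = None
    name: Optional[str] = None
    birth_date: Optional[str] = None       # ISO 8601 date string
    sex_code: Optional[str] = None         # value set sex_iso22220
    ethnicity_code: Optional[str] = None   # HL7 v3 race lexical code, e.g. 2040-4


class OrderInfo(BaseModel):
    order_id: Optional[str] = None
    order_date: Optional[str] = None
    ordering_clinician: Optional[str] = None
    legally_authorized_orderer: Optional[str] = None
    performing_laboratory: Optional[str] = None


class SpecimenInfo(BaseModel):
    specimen_id: Optional[str] = None
    sample_type: Optional[str] = None
    collection_date: Optional[str] = None


class ReportMeta(BaseModel):
    report_id: Optional[str] = None
    report_status: Optional[str] = None
    test_code: Optional[str] = None
    issued_date: Optional[str] = None
    interpretation_summary: Optional[str] = None
    assessed_condition: Optional[str] = None


class ClassificationTriple(BaseModel):
    model_config = ConfigDict(frozen=True)

    tier: str
    pathogeny: str
    clinical_relevance: str

    @model_validator(mode="after")
    def _codes_in_value_sets(self) -> "ClassificationTriple":
        for name, code in (("tier", self.tier), ("pathogeny", self.pathogeny),
                           ("clinical_relevance", self.clinical_relevance)):
            if code not in value_set(name):
                raise ValueError(f"{name} code {code!r} not in value set {name!r}")
        return self


class VariantRecord(BaseModel):
    gene_hgnc_id: str
    gene_symbol: str
    hgvs_notation: str                      # raw dialect string, kept verbatim
    cdna_change: str = ""                   # normalized, derived if omitted
    protein_change: Optional[str] = None
    variant_effect: Optional[str] = None
    variant_db_id: Optional[str] = None
    classification: Optional[ClassificationTriple] = None
    genomic_source_class: Optional[str] = None
    result_status: Optional[str] = None
    variant_test_code: Optional[str] = None
    variant_interpretation: Optional[str] = None
    variant_comment: Optional[str] = None
    test_method: Optional[str] = None
    observation_date: Optional[str] = None

    @field_validator("gene_hgnc_id")
    @classmethod
    def _hgnc_pattern(cls, v: str) -> str:
        if not HGNC_ID_RE.match(v):
            raise ValueError(f"gene id {v!r} does not match 'HGNC:<digits>'")
        return v

    @model_validator(mode="after")
    def _derive_changes(self) -> "VariantRecord":
        if not self.cdna_change:
            cdna, protein = parse_variant_notation(self.hgvs_notation)
            object.__setattr__(self, "cdna_change", cdna)
            if self.protein_change is None:
                object.__setattr__(self, "protein_change", protein)
        if not self.cdna_change.startswith(("c.", "g.")):
            raise ValueError(f"cdna_change must begin 'c.' or 'g.': {self.cdna_change!r}")
        if self.protein_change is not None and not self.protein_change.startswith("p."):
            raise ValueError(f"protein_change must begin 'p.': {self.protein_change!r}")
        return self


class SequencingReport(BaseModel):
    subject: Optional[SubjectInfo] = None
    order: Optional[OrderInfo] = None
    specimen: Optional[SpecimenInfo] = None
    report_meta: Optional[ReportMeta] = None
    variants: list[VariantRecord] = Field(default_factory=list)
    recommended_treatments: list[str] = Field(default_factory=list)
    research: dict[str, Any] = Field(default_factory=dict)
    #: explicit negative result: the assay ran and no reportable variant was
    #: found; only then are the per-variant required elements waived.
    no_variants_reported: bool = False


# -------------------------------------------------------------- grammars

_CLASSIFICATION_RE = re.compile(
    r"^\s*(?P<tier>Tier\s*\d)\s*\(\s*(?P<pathogeny>[^,()]+?)\s*,"
    r"\s*(?P<relevance>[^,()]+?)\s*\)\s*$"
)


def parse_classification(text: str) -> ClassificationTriple:
    """Split ``"<Tier> (<Pathogeny>, <ClinicalRelevance>)"`` into its triple."""
    m = _CLASSIFICATION_RE.match(text)
    if not m:
        raise GrammarError(
            f"classification {text!r} does not match '<Tier> (<Pathogeny>, "
            "<ClinicalRelevance>)'"
        )
    tier = re.sub(r"\s+", " ", m.group("tier")).strip()
    if " " not in tier:  # accept "Tier1"
        tier = tier.replace("Tier", "Tier ")
    pathogeny = m.group("pathogeny").strip()
    relevance = m.group("relevance").strip()
    for vs_name, code in (("tier", tier), ("pathogeny", pathogeny),
                          ("clinical_relevance", relevance)):
        if code not in value_set(vs_name):
            raise GrammarError(f"{vs_name} component {code!r} not in value set")
    return ClassificationTriple(tier=tier, pathogeny=pathogeny,
                                clinical_relevance=relevance)


def format_classification(triple: ClassificationTriple) -> str:
    """Emit the canonical printed form; inverse of :func:`parse_classification`."""
    return f"{triple.tier} ({triple.pathogeny}, {triple.clinical_relevance})"


def parse_variant_notation(text: str) -> tuple[str, Optional[str]]:
    """Split the ``"<cdna>_<protein>"`` dialect into normalized HGVS strings.

    Spaces around ``>`` are stripped; the protein part is optional.
    """
    parts = [p.strip() for p in text.split("_")]
    cdna = re.sub(r"\s*>\s*", ">", parts[0])
    if not cdna.startswith(("c.", "g.")):
        raise GrammarError(
            f"variant notation {text!r}: expected a 'c.' or 'g.' prefixed change"
        )
    protein: Optional[str] = None
    if len(parts) > 1 and parts[1]:
        protein = re.sub(r"\s+", "", parts[1])
        if not protein.startswith("p."):
            raise GrammarError(
                f"variant notation {text!r}: protein part must begin 'p.'"
            )
    return cdna, protein


# ------------------------------------------------------- element access
#
# One accessor per registry element: report-scoped elements read from the
# report document, variant-scoped ones (genetic_variation.*) from a single
# VariantRecord.  The same table drives validation presence checks, the
# builder and the coverage audit.

def _sub(attr):
    def get(report: SequencingReport, block: str = attr.split(".")[0],
            field: str = attr.split(".")[1]):
        obj = getattr(report, block)
        return getattr(obj, field) if obj is not None else None
    return get


REPORT_GETTERS = {
    "order.order_id": _sub("order.order_id"),
    "order.order_date": _sub("order.order_date"),
    "order.ordering_clinician": _sub("order.ordering_clinician"),
    "order.legally_authorized_orderer": _sub("order.legally_authorized_orderer"),
    "order.performing_laboratory": _sub("order.performing_laboratory"),
    "subject.identifier": _sub("subject.identifier"),
    "subject.name": _sub("subject.name"),
    "subject.birth_date": _sub("subject.birth_date"),
    "subject.sex": _sub("subject.sex_code"),
    "subject.ethnicity": _sub("subject.ethnicity_code"),
    "specimen.specimen_id": _sub("specimen.specimen_id"),
    "specimen.sample_type": _sub("specimen.sample_type"),
    "specimen.collection_date": _sub("specimen.collection_date"),
    "report.report_id": _sub("report_meta.report_id"),
    "report.report_status": _sub("report_meta.report_status"),
    "report.test_code": _sub("report_meta.test_code"),
    "report.issued_date": _sub("report_meta.issued_date"),
    "report.interpretation_summary": _sub("report_meta.interpretation_summary"),
    "report.assessed_condition": _sub("report_meta.assessed_condition"),
    "treatment.recommended_treatment":
        lambda r: r.recommended_treatments or None,
}

VARIANT_GETTERS = {
    "genetic_variation.gene_symbol": lambda v: (v.gene_hgnc_id, v.gene_symbol),
    "genetic_variation.notation": lambda v: v.hgvs_notation,
    "genetic_variation.variant_effect": lambda v: v.variant_effect,
    "genetic_variation.variant_db_id": lambda v: v.variant_db_id,
    "genetic_variation.classification": lambda v: v.classification,
    "genetic_variation.genomic_source_class": lambda v: v.genomic_source_class,
    "genetic_variation.result_status": lambda v: v.result_status,
    "genetic_variation.variant_test_code": lambda v: v.variant_test_code,
    "genetic_variation.variant_interpretation": lambda v: v.variant_interpretation,
    "genetic_variation.variant_comment": lambda v: v.variant_comment,
    "genetic_variation.test_method": lambda v: v.test_method,
    "genetic_variation.observation_date": lambda v: v.observation_date,
}


def element_value(report: SequencingReport, element_id: str,
                  variant: VariantRecord | None = None) -> Any:
    """The report's value for one element, or None when unpopulated."""
    if element_id in VARIANT_GETTERS:
        return VARIANT_GETTERS[element_id](variant) if variant is not None else None
    if element_id in REPORT_GETTERS:
        return REPORT_GETTERS[element_id](report)
    return report.research.get(element_id)


# ----------------------------------------------------------- the builder

_TREATMENT_EXT = "diagnosticReport-recommendedTreatment"


def _top_extension_url(placement: str) -> str | None:
    """Absolute URL for the first ``ext:`` step of a placement, if any.

    Sub-extension slots share one top-level parent extension (e.g. the
    classification triple), so the URL is rebuilt from the step name rather
    than taken from the slot's own (sub-)definition URL.
    """
    from .mapping import EXTENSION_BASE_URL

    for step in placement.split("/"):
        if step.startswith("ext:"):
            return EXTENSION_BASE_URL + step[4:]
    return None


def _classification_component(row: MappingRow, triple: ClassificationTriple) -> str:
    name = row.target.fhir_path.rsplit(".", 1)[-1]
    return {"Tier": triple.tier, "Pathogeny": triple.pathogeny,
            "ClinicalRelavance": triple.clinical_relevance}[name]


def build_bundle(report: SequencingReport) -> Bundle:
    """Assemble the FHIR collection bundle for a conformant report."""
    from .validation import validate_report  # local import breaks the cycle

    issues = [i for i in validate_report(report) if i.severity == "error"]
    if issues:
        raise BuildError(
            f"report fails validation with {len(issues)} error(s)", issues
        )

    patient = make_resource("Patient", logical_id="patient-1")
    order = make_resource("ProcedureRequest", logical_id="order-1")
    dr = make_resource("DiagnosticReport", logical_id="report-1")
    observations = [
        make_resource("Observation", logical_id=f"variant-{i + 1}")
        for i in range(len(report.variants))
    ]
    medications = [
        make_resource("Medication", logical_id=f"medication-{i + 1}")
        for i in range(len(report.recommended_treatments))
    ]
    research_keys = set(report.research)
    need = {
        rt: any(
            r.element_id in research_keys and r.target.resource_type == rt
            for r in load_mapping_table() if r.field_class == "optional"
        )
        for rt in ("MolecularSequence", "Device", "Condition")
    }
    molseq = make_resource("MolecularSequence", logical_id="sequence-1") \
        if need["MolecularSequence"] else None
    device = make_resource("Device", logical_id="device-1") if need["Device"] else None
    condition = make_resource("Condition", logical_id="condition-1") \
        if need["Condition"] else None

    instances: dict[str, FhirResource | None] = {
        "Patient": patient, "ProcedureRequest": order, "DiagnosticReport": dr,
        "MolecularSequence": molseq, "Device": device, "Condition": condition,
    }

    for row in load_mapping_table():
        rt = row.target.resource_type
        if row.element_id == "treatment.recommended_treatment":
            continue  # handled below, one slot instance per treatment
        placement = row.placement
        url = _top_extension_url(placement)
        deref = "/@Patient/" in placement
        if deref:
            placement = "Patient/" + placement.split("/@Patient/", 1)[1]
        if rt == "Observation":
            value_src = row.element_id
            for idx, obs in enumerate(observations):
                if value_src in VARIANT_GETTERS:
                    val = element_value(report, value_src, report.variants[idx])
                elif row.field_class == "optional":
                    if idx > 0:   # research annotations ride the first variant
                        continue
                    val = element_value(report, value_src)
                else:
                    val = element_value(report, value_src)
                if val is None:
                    continue
                val = _encode(row, val)
                set_placement(obs, placement, val, ext_url=url)
            continue
        target = patient if deref else instances.get(rt)
        if target is None:
            continue
        val = element_value(report, row.element_id)
        if val is None:
            continue
        if placement.endswith("/gender"):
            val = SEX_CODE_TO_GENDER.get(val, "unknown")
        val = _encode(row, val)
        set_placement(target, placement, val, ext_url=url)

    # treatments: free-standing Medication entries referenced from the report
    treat_url = next(d.url for d in extension_definitions() if d.name == _TREATMENT_EXT)
    for med, name in zip(medications, report.recommended_treatments):
        set_placement(med, "Medication/code/text", name)
        dr.extensions.append(
            {"url": treat_url, "valueReference": {"reference": med.reference}}
        )

    # structural wiring
    dr.body["subject"] = {"reference": patient.reference}
    dr.body["result"] = [{"reference": o.reference} for o in observations]
    order.body["subject"] = {"reference": patient.reference}
    for obs in observations:
        obs.body["subject"] = {"reference": patient.reference}
    if molseq is not None:
        molseq.body["patient"] = {"reference": patient.reference}
        if device is not None:
            molseq.body["device"] = {"reference": device.reference}
    if condition is not None:
        condition.body["subject"] = {"reference": patient.reference}

    entries = [patient, order, dr, *observations, *medications]
    entries += [r for r in (molseq, device, condition) if r is not None]
    return Bundle(bundle_type="collection", logical_id="sequencing-report-bundle",
                  entries=entries)


def _encode(row: MappingRow, val: Any) -> Any:
    """Element value → the JSON leaf stored at the row's placement."""
    eid = row.element_id
    if eid == "genetic_variation.gene_symbol":
        hgnc_id, symbol = val
        return {"system": GENE_SYSTEM, "code": hgnc_id, "display": symbol}
    if eid == "genetic_variation.classification":
        return _classification_component(row, val)
    return val


# --------------------------------------------------------- the extractor

def extract_report(bundle: Bundle) -> SequencingReport:
    """Invert :func:`build_bundle` on its image."""
    return extract_report_detailed(bundle)[0]


def extract_report_detailed(bundle: Bundle) -> tuple[SequencingReport, list[dict]]:
    """Extract the report plus a side list of unmapped extensions."""
    drs = bundle.resources("DiagnosticReport")
    if not drs:
        raise ExtractionError("bundle contains no DiagnosticReport")
    dr = drs[0]

    observations: list[FhirResource] = []
    for ref in dr.body.get("result", []):
        res = bundle.resolve(ref.get("reference", ""))
        if res is not None and res.resource_type == "Observation":
            observations.append(res)
    if not observations:
        observations = bundle.resources("Observation")

    instances: dict[str, FhirResource | None] = {
        "DiagnosticReport": dr,
        "Patient": _first(bundle, "Patient"),
        "ProcedureRequest": _first(bundle, "ProcedureRequest"),
        "MolecularSequence": _first(bundle, "MolecularSequence"),
        "Device": _first(bundle, "Device"),
        "Condition": _first(bundle, "Condition"),
        "Observation": observations[0] if observations else None,
    }

    values: dict[str, Any] = {}
    for row in load_mapping_table():
        eid = row.element_id
        if eid in values or eid in VARIANT_GETTERS:
            continue
        if eid == "treatment.recommended_treatment":
            continue
        src = instances.get(row.target.resource_type)
        if src is None:
            continue
        raw = walk_placement(bundle, src, row.placement)
        if raw is None:
            continue
        if row.placement.endswith("/gender"):
            continue  # the raw ISO sex code rides the Patient extension slot
        values[eid] = raw

    variants = [_variant_from_observation(bundle, o) for o in observations]
    variants = [v for v in variants if v is not None]

    treatments: list[str] = []
    for ext in dr.extensions:
        if ext.get("url", "").rsplit("/", 1)[-1] == _TREATMENT_EXT:
            med = bundle.resolve(ext.get("valueReference", {}).get("reference", ""))
            if med is not None:
                treatments.append(med.body.get("code", {}).get("text", ""))

    research = {
        s.element_id: values[s.element_id]
        for s in load_element_registry()
        if s.field_class == "optional" and s.element_id in values
    }

    def block(model, mapping):
        kwargs = {attr: values.get(eid) for eid, attr in mapping.items()}
        return model(**kwargs) if any(v is not None for v in kwargs.values()) else None

    report = SequencingReport(
        subject=block(SubjectInfo, {
            "subject.identifier": "identifier", "subject.name": "name",
            "subject.birth_date": "birth_date", "subject.sex": "sex_code",
            "subject.ethnicity": "ethnicity_code"}),
        order=block(OrderInfo, {
            "order.order_id": "order_id", "order.order_date": "order_date",
            "order.ordering_clinician": "ordering_clinician",
            "order.legally_authorized_orderer": "legally_authorized_orderer",
            "order.performing_laboratory": "performing_laboratory"}),
        specimen=block(SpecimenInfo, {
            "specimen.specimen_id": "specimen_id",
            "specimen.sample_type": "sample_type",
            "specimen.collection_date": "collection_date"}),
        report_meta=block(ReportMeta, {
            "report.report_id": "report_id", "report.report_status": "report_status",
            "report.test_code": "test_code", "report.issued_date": "issued_date",
            "report.interpretation_summary": "interpretation_summary",
            "report.assessed_condition": "assessed_condition"}),
        variants=variants,
        recommended_treatments=treatments,
        research=research,
        no_variants_reported=not variants,
    )
    return report, _unmapped_extensions(bundle)


def _first(bundle: Bundle, rtype: str) -> FhirResource | None:
    found = bundle.resources(rtype)
    return found[0] if found else None


def _variant_from_observation(bundle: Bundle,
                              obs: FhirResource) -> VariantRecord | None:
    vals: dict[str, Any] = {}
    for row in load_mapping_table():
        if row.element_id not in VARIANT_GETTERS:
            continue
        raw = walk_placement(bundle, obs, row.placement)
        if raw is not None:
            vals.setdefault(row.element_id, {})[row.target.fhir_path] = raw
    gene = next(iter(vals.get("genetic_variation.gene_symbol", {}).values()), None)
    notation = next(iter(vals.get("genetic_variation.notation", {}).values()), None)
    if gene is None or notation is None:
        return None
    cls_parts = vals.get("genetic_variation.classification", {})
    triple = None
    if len(cls_parts) == 3:
        by_name = {p.rsplit(".", 1)[-1]: v for p, v in cls_parts.items()}
        triple = ClassificationTriple(
            tier=by_name["Tier"], pathogeny=by_name["Pathogeny"],
            clinical_relevance=by_name["ClinicalRelavance"])

    def one(eid):
        return next(iter(vals.get(eid, {}).values()), None)

    return VariantRecord(
        gene_hgnc_id=gene.get("code", ""),
        gene_symbol=gene.get("display", ""),
        hgvs_notation=notation,
        variant_effect=one("genetic_variation.variant_effect"),
        variant_db_id=one("genetic_variation.variant_db_id"),
        classification=triple,
        genomic_source_class=one("genetic_variation.genomic_source_class"),
        result_status=one("genetic_variation.result_status"),
        variant_test_code=one("genetic_variation.variant_test_code"),
        variant_interpretation=one("genetic_variation.variant_interpretation"),
        variant_comment=one("genetic_variation.variant_comment"),
        test_method=one("genetic_variation.test_method"),
        observation_date=one("genetic_variation.observation_date"),
    )


def _unmapped_extensions(bundle: Bundle) -> list[dict]:
    known = {d.url for d in extension_definitions()}
    known_names = {d.url.rsplit("/", 1)[-1] for d in extension_definitions()}
    # the classification triple's complex parent and its relative sub-names
    known_names |= {"observation-classificationVariants",
                    "Tier", "Pathogeny", "ClinicalRelavance"}
    out = []
    for res in bundle.entries:
        for ext in res.extensions:
            url = ext.get("url", "")
            if url not in known and url.rsplit("/", 1)[-1] not in known_names:
                out.append({"resource": res.reference, "url": url})
    return out


# -------------------------------------------------------- document files

def report_to_dict(report: SequencingReport) -> dict[str, Any]:
    """Serialize to the element-id-keyed report document."""
    doc: dict[str, Any] = {}
    for eid in REPORT_GETTERS:
        if eid == "treatment.recommended_treatment":
            continue
        val = REPORT_GETTERS[eid](report)
        if val is not None:
            doc[eid] = val
    doc["variants"] = [
        {
            "genetic_variation.gene_symbol": {
                "hgnc_id": v.gene_hgnc_id, "symbol": v.gene_symbol},
            "genetic_variation.notation": v.hgvs_notation,
            **{f"genetic_variation.{k}": getattr(v, k)
               for k in ("variant_effect", "variant_db_id", "genomic_source_class",
                         "result_status", "variant_test_code",
                         "variant_interpretation", "variant_comment",
                         "test_method", "observation_date")
               if getattr(v, k) is not None},
            **({"genetic_variation.classification":
                format_classification(v.classification)}
               if v.classification else {}),
        }
        for v in report.variants
    ]
    doc["treatment.recommended_treatment"] = list(report.recommended_treatments)
    if report.research:
        doc["research"] = copy.deepcopy(report.research)
    if report.no_variants_reported:
        doc["no_variants_reported"] = True
    return doc


def report_from_dict(doc: dict[str, Any]) -> SequencingReport:
    def pick(model, mapping):
        kwargs = {attr: doc.get(eid) for eid, attr in mapping.items()}
        return model(**kwargs) if any(v is not None for v in kwargs.values()) else None

    variants = []
    for vd in doc.get("variants", []):
        gene = vd.get("genetic_variation.gene_symbol", {})
        cls_text = vd.get("genetic_variation.classification")
        variants.append(VariantRecord(
            gene_hgnc_id=gene.get("hgnc_id", ""),
            gene_symbol=gene.get("symbol", ""),
            hgvs_notation=vd.get("genetic_variation.notation", ""),
            classification=parse_classification(cls_text) if cls_text else None,
            **{k: vd.get(f"genetic_variation.{k}")
               for k in ("variant_effect", "variant_db_id", "genomic_source_class",
                         "result_status", "variant_test_code",
                         "variant_interpretation", "variant_comment",
                         "test_method", "observation_date")},
        ))
    return SequencingReport(
        subject=pick(SubjectInfo, {
            "subject.identifier": "identifier", "subject.name": "name",
            "subject.birth_date": "birth_date", "subject.sex": "sex_code",
            "subject.ethnicity": "ethnicity_code"}),
        order=pick(OrderInfo, {
            "order.order_id": "order_id", "order.order_date": "order_date",
            "order.ordering_clinician": "ordering_clinician",
            "order.legally_authorized_orderer": "legally_authorized_orderer",
            "order.performing_laboratory": "performing_laboratory"}),
        specimen=pick(SpecimenInfo, {
            "specimen.specimen_id": "specimen_id",
            "specimen.sample_type": "sample_type",
            "specimen.collection_date": "collection_date"}),
        report_meta=pick(ReportMeta, {
            "report.report_id": "report_id", "report.report_status": "report_status",
            "report.test_code": "test_code", "report.issued_date": "issued_date",
            "report.interpretation_summary": "interpretation_summary",
            "report.assessed_condition": "assessed_condition"}),
        variants=variants,
        recommended_treatments=list(doc.get("treatment.recommended_treatment", [])),
        research=dict(doc.get("research", {})),
        no_variants_reported=bool(doc.get("no_variants_reported", False)),
    )


def report_from_text(text: str) -> SequencingReport:
    """Parse a report document from JSON (or YAML) text."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise GrammarError("report document must be a JSON/YAML object")
    return report_from_dict(doc)
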