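"""Mapping table: targets, slot statistics, extension registry, I/O."""

from collections import Counter

import pytest

from seqreport import extension_definitions, map_element, mapping_statistics
from seqreport.errors import NotFoundError
from seqreport.mapping import (
    export_mapping_csv,
    export_mapping_json,
    import_mapping_csv,
    load_mapping_table,
)

EXPECTED_COUNTS = {
    ("required", "ProcedureRequest"): (3, 0),
    ("required", "DiagnosticReport"): (12, 5),
    ("required", "Observation"): (8, 8),
    ("required", "Medication"): (1, 0),
    ("required", "Patient"): (2, 2),
    ("optional", "Condition"): (1, 0),
    ("optional", "DiagnosticReport"): (2, 2),
    ("optional", "MolecularSequence"): (16, 10),
    ("optional", "Observation"): (6, 6),
    ("optional", "Device"): (3, 3),
}


@pytest.mark.parametrize(
    "element_id, resource, path, kind",
    [
        ("genetic_variation.gene_symbol", "Observation",
         "Observation.extension(observation-geneticsGene)", "extension"),
        ("subject.ethnicity", "DiagnosticReport",
         "DiagnosticReport.subject(patient).extension(ethnicity)", "extension"),
        ("subject.name", "DiagnosticReport",
         "DiagnosticReport.subject(patient)", "reuse"),
        ("genetic_variation.variant_db_id", "Observation",
         "Observation.extension(observation-geneticsDNAVariantId)", "extension"),
    ],
)
def test_map_element_targets(element_id, resource, path, kind):
    target = map_element(element_id)
    assert target.resource_type == resource
    assert target.fhir_path == path
    assert target.mapping_kind == kind
    assert (kind == "extension") == bool(target.extension_url)


def test_map_element_unknown():
    with pytest.raises(NotFoundError):
        map_element("no.such.element")


def test_slot_statistics_match_published_counts():
    st = mapping_statistics()
    for (fclass, rtype), expected in EXPECTED_COUNTS.items():
        table = st.required if fclass == "required" else st.optional
        assert table[rtype] == expected, (fclass, rtype)
    assert st.required_total == (26, 15)
    assert st.optional_total == (28, 21)
    assert st.grand_total == 90


def test_statistics_on_empty_table_are_zero():
    st = mapping_statistics(rows=[])
    assert st.required_total == (0, 0)
    assert st.optional_total == (0, 0)
    assert st.grand_total == 0


def test_required_and_optional_resource_sets():
    rows = load_mapping_table()
    req = {r.target.resource_type for r in rows if r.field_class == "required"}
    opt = {r.target.resource_type for r in rows if r.field_class == "optional"}
    assert req == {"ProcedureRequest", "DiagnosticReport", "Observation",
                   "Medication", "Patient"}
    assert opt == {"Condition", "DiagnosticReport", "MolecularSequence",
                   "Observation", "Device"}


def test_extension_path_marking_is_consistent():
    for r in load_mapping_table():
        is_ext = r.target.mapping_kind == "extension"
        assert is_ext == ("extension(" in r.target.fhir_path)
        assert is_ext == bool(r.target.extension_url)
        base = r.target.fhir_path.split(".")[0]
        assert base == r.target.resource_type


def test_extension_definitions_registry():
    defs = extension_definitions()
    urls = [d.url for d in defs]
    assert len(urls) == len(set(urls))
    names = {d.name: d for d in defs}
    assert names["observation-geneticsDNAVariantId"].host_resource == "Observation"
    for sub in ("Tier", "Pathogeny", "ClinicalRelavance"):
        assert f"observation-classificationVariants.{sub}" in names
    # 15 + 21 extension slot usages over the registered definitions
    ext_rows = [r for r in load_mapping_table()
                if r.target.mapping_kind == "extension"]
    assert len(ext_rows) == 36
    registered = set(urls)
    assert all(r.target.extension_url in registered for r in ext_rows)


def test_mapping_csv_roundtrip_is_lossless():
    text = export_mapping_csv()
    reimported = import_mapping_csv(text)
    assert sorted(reimported, key=repr) == sorted(load_mapping_table(), key=repr)
    # export is byte-stable
    assert export_mapping_csv() == text


def test_mapping_csv_accepts_servicerequest_alias():
    text = export_mapping_csv().replace("ProcedureRequest,ProcedureRequest.",
                                        "ServiceRequest,ProcedureRequest.")
    rows = import_mapping_csv(text)
    stats = Counter(r.target.resource_type for r in rows)
    assert stats["ProcedureRequest"] == 3


def test_mapping_json_export_parses():
    import json

    payload = json.loads(export_mapping_json())
    assert len(payload) == 90
    assert {p["field_class"] for p in payload} == {"required", "optional"}
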