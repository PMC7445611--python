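"""Composite grammars, bundle building and extraction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqreport import (
    ClassificationTriple,
    SequencingReport,
    build_bundle,
    extract_report,
    extract_report_detailed,
    format_classification,
    parse_classification,
    parse_variant_notation,
    validate_bundle_refs,
    value_set,
    worked_example,
)
from seqreport.errors import BuildError, ExtractionError, GrammarError
from seqreport.fhir_model import Bundle, add_extension
from seqreport.report_builder import report_from_dict, report_to_dict

from conftest import bundle_as_json, independent_walk


# ------------------------------------------------------ classification

@pytest.mark.parametrize("text, expected", [
    ("Tier 1 (Pathogenic, Identified)", ("Tier 1", "Pathogenic", "Identified")),
    ("Tier 3 (Unknown significance, Uncertain)",
     ("Tier 3", "Unknown significance", "Uncertain")),
    ("  Tier 2  ( Likely pathogenic ,  Likely identified )  ",
     ("Tier 2", "Likely pathogenic", "Likely identified")),
])
def test_parse_classification(text, expected):
    triple = parse_classification(text)
    assert (triple.tier, triple.pathogeny, triple.clinical_relevance) == expected


@pytest.mark.parametrize("text", [
    "Pathogenic",                          # no tier / parentheses
    "Tier 1 (Wrong, Identified)",          # out-of-set pathogeny
    "Tier 1 (Pathogenic, Sometimes)",      # out-of-set relevance
    "Tier 9 (Pathogenic, Identified)",     # out-of-set tier
])
def test_parse_classification_rejects(text):
    with pytest.raises(GrammarError):
        parse_classification(text)


def test_format_classification_canonical_form():
    triple = ClassificationTriple(tier="Tier 1", pathogeny="Pathogenic",
                                  clinical_relevance="Identified")
    assert format_classification(triple) == "Tier 1 (Pathogenic, Identified)"


@settings(max_examples=80, derandomize=True)
@given(
    tier=st.sampled_from([c for c, _ in value_set("tier").codes]),
    pathogeny=st.sampled_from([c for c, _ in value_set("pathogeny").codes]),
    relevance=st.sampled_from([c for c, _ in value_set("clinical_relevance").codes]),
)
def test_classification_parse_format_inverse(tier, pathogeny, relevance):
    triple = ClassificationTriple(tier=tier, pathogeny=pathogeny,
                                  clinical_relevance=relevance)
    assert parse_classification(format_classification(triple)) == triple


def test_triple_rejects_out_of_set_code():
    with pytest.raises(ValueError):
        ClassificationTriple(tier="Tier 1", pathogeny="Bad",
                             clinical_relevance="Identified")


# ---------------------------------------------------- variant notation

@pytest.mark.parametrize("text, cdna, protein", [
    ("c.1799T > A_p.V600E", "c.1799T>A", "p.V600E"),
    ("c.35G>A", "c.35G>A", None),
    ("c.2573T>G_p.L858R", "c.2573T>G", "p.L858R"),
    ("g.140453136A > T", "g.140453136A>T", None),
])
def test_parse_variant_notation(text, cdna, protein):
    assert parse_variant_notation(text) == (cdna, protein)


@pytest.mark.parametrize("text", ["V600E", "p.V600E", "1799T>A"])
def test_parse_variant_notation_rejects_missing_prefix(text):
    with pytest.raises(GrammarError):
        parse_variant_notation(text)


# ------------------------------------------------------------ building

def test_worked_example_bundle_carries_published_values(example_bundle):
    doc = bundle_as_json(example_bundle)
    observations = [e["resource"] for e in doc["entry"]
                    if e["resource"]["resourceType"] == "Observation"]
    assert len(observations) == 1
    obs = observations[0]
    by_name = {e["url"].split("/")[-1]: e for e in obs["extension"]}
    gene = by_name["observation-geneticsGene"]["valueCodeableConcept"]["coding"][0]
    assert gene["code"] == "HGNC:1097"
    assert gene["display"] == "BRAF"
    assert by_name["observation-geneticsDNAVariantId"]["valueString"] == "COSM476"
    assert (by_name["observation-geneticsDNASequenceVariantName"]["valueString"]
            == "c.1799T > A_p.V600E")
    triple = {e["url"]: e["valueString"]
              for e in by_name["observation-classificationVariants"]["extension"]}
    assert triple == {"Tier": "Tier 1", "Pathogeny": "Pathogenic",
                      "ClinicalRelavance": "Identified"}


def test_worked_example_roundtrip(example_report, example_bundle):
    assert extract_report(example_bundle) == example_report


def test_bundle_references_close(example_bundle):
    assert validate_bundle_refs(example_bundle) == []


def test_zero_variant_negative_report_builds():
    report = worked_example()
    report.variants = []
    report.no_variants_reported = True
    bundle = build_bundle(report)
    assert bundle.resources("DiagnosticReport")
    assert bundle.resources("Observation") == []


def test_build_refuses_invalid_report():
    report = worked_example()
    report.subject = None
    with pytest.raises(BuildError) as exc:
        build_bundle(report)
    assert any(i.code == "missing-required" for i in exc.value.issues)


def test_extract_requires_diagnostic_report():
    with pytest.raises(ExtractionError):
        extract_report(Bundle())


def test_unknown_extension_lands_in_unmapped_list(example_report):
    bundle = build_bundle(example_report)
    obs = bundle.resources("Observation")[0]
    add_extension(obs, "https://elsewhere.example.org/ext/unrelated", "x")
    report, unmapped = extract_report_detailed(bundle)
    assert report == example_report
    assert unmapped == [{"resource": obs.reference,
                         "url": "https://elsewhere.example.org/ext/unrelated"}]


def test_corpus_roundtrip_identity(corpus):
    for report in corpus:
        bundle = build_bundle(report)
        assert validate_bundle_refs(bundle) == []
        assert extract_report(bundle) == report


def test_field_placement_against_independent_walker(corpus):
    """Walking each mapped slot with a brute-force interpreter recovers the
    report's value for every populated element."""
    from seqreport.iso_schema import SEX_CODE_TO_GENDER
    from seqreport.mapping import load_mapping_table
    from seqreport.report_builder import VARIANT_GETTERS, element_value

    report = corpus[0]
    bundle = build_bundle(report)
    doc = bundle_as_json(bundle)
    instances = {}
    for entry in doc["entry"]:
        instances.setdefault(entry["resource"]["resourceType"], []).append(
            entry["resource"])

    for row in load_mapping_table():
        if row.element_id == "treatment.recommended_treatment":
            continue  # one slot instance per treatment, checked below
        candidates = instances.get(row.target.resource_type, [])
        walked = [independent_walk(doc, c, row.placement) for c in candidates]
        walked = [w for w in walked if w is not None]
        if row.element_id in VARIANT_GETTERS:
            for variant in report.variants:
                val = element_value(report, row.element_id, variant)
                if val is None:
                    continue
                if row.element_id == "genetic_variation.gene_symbol":
                    assert any(w["code"] == val[0] and w["display"] == val[1]
                               for w in walked), row.placement
                elif row.element_id == "genetic_variation.classification":
                    part = row.target.fhir_path.rsplit(".", 1)[-1]
                    expect = {"Tier": val.tier, "Pathogeny": val.pathogeny,
                              "ClinicalRelavance": val.clinical_relevance}[part]
                    assert expect in walked, row.placement
                else:
                    assert val in walked, row.placement
        else:
            val = element_value(report, row.element_id)
            if val is None:
                continue
            if row.placement.endswith("/gender"):
                val = SEX_CODE_TO_GENDER[val]
            assert val in walked, (row.element_id, row.placement, walked)

    # each recommended treatment is reachable as a referenced Medication
    dr = instances["DiagnosticReport"][0]
    refs = [e["valueReference"]["reference"] for e in dr.get("extension", [])
            if e["url"].endswith("recommendedTreatment")]
    meds = [independent_walk(doc, m, "Medication/code/text")
            for m in instances.get("Medication", [])]
    assert len(refs) == len(report.recommended_treatments)
    assert sorted(meds) == sorted(report.recommended_treatments)


def test_report_document_roundtrip(corpus):
    for report in corpus[:5]:
        assert report_from_dict(report_to_dict(report)) == report
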