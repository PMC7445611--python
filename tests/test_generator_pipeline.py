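"""Synthetic generator contracts and the end-to-end pipeline property."""

import pytest

from seqreport import (
    build_bundle,
    extract_report,
    render_summary,
    validate_bundle_refs,
    validate_report,
    value_set,
    worked_example,
)
from seqreport.errors import SeqReportError
from seqreport.generator import GeneratorConfig, gene_micro_list, generate_reports
from seqreport.repository import ResourceRepository


def test_same_seed_yields_identical_corpora():
    cfg = GeneratorConfig(seed=42, n_reports=8, include_research_block=0.7)
    assert generate_reports(cfg) == generate_reports(cfg)


def test_different_seed_differs():
    a = generate_reports(GeneratorConfig(seed=1, n_reports=4))
    b = generate_reports(GeneratorConfig(seed=2, n_reports=4))
    assert a != b


def test_zero_missingness_corpus_validates_cleanly():
    reports = generate_reports(GeneratorConfig(seed=3, n_reports=50,
                                               missingness=0.0))
    assert len(reports) == 50
    for report in reports:
        assert validate_report(report) == []


def test_required_corruption_flag_produces_errors():
    reports = generate_reports(GeneratorConfig(seed=5, n_reports=10,
                                               corrupt_required=True,
                                               missingness=0.5))
    for report in reports:
        assert any(i.severity == "error" for i in validate_report(report))


def test_invalid_config_range_rejected():
    with pytest.raises(SeqReportError):
        GeneratorConfig(seed=1, variants_per_report=(3, 1))
    with pytest.raises(Exception):
        GeneratorConfig(seed=1, n_reports=0)


def test_generated_codes_belong_to_their_value_sets(corpus):
    sex = value_set("sex_iso22220")
    race = value_set("hl7_race")
    tier = value_set("tier")
    pathogeny = value_set("pathogeny")
    relevance = value_set("clinical_relevance")
    genes = {g["hgnc_id"] for g in gene_micro_list()}
    for report in corpus:
        assert report.subject.sex_code in sex
        assert report.subject.ethnicity_code in race
        for v in report.variants:
            assert v.gene_hgnc_id in genes
            assert v.classification.tier in tier
            assert v.classification.pathogeny in pathogeny
            assert v.classification.clinical_relevance in relevance


def test_missingness_applies_only_to_optional_fields():
    full = generate_reports(GeneratorConfig(seed=9, n_reports=10,
                                            include_research_block=1.0))
    thinned = generate_reports(GeneratorConfig(seed=9, n_reports=10,
                                               include_research_block=1.0,
                                               missingness=0.6))
    assert sum(len(r.research) for r in thinned) < sum(len(r.research) for r in full)
    for report in thinned:
        assert validate_report(report) == []  # required fields untouched


def test_end_to_end_pipeline(corpus):
    """generate → validate → build → store → search → extract → render."""
    repo = ResourceRepository()
    for i, report in enumerate(corpus[:10]):
        assert [x for x in validate_report(report) if x.severity == "error"] == []
        bundle = build_bundle(report)
        assert validate_bundle_refs(bundle) == []
        # re-key ids so several bundles can share the store
        for entry in bundle.entries:
            entry.logical_id = f"{entry.logical_id}-r{i}"
        for entry in bundle.entries:  # fix internal refs after re-keying
            _rewrite_refs(entry.body, f"-r{i}")
            for ext in entry.extensions:
                _rewrite_refs(ext, f"-r{i}")
        repo.create(bundle)
        hits = repo.search("Observation", subject=f"Patient/patient-1-r{i}")
        assert len(hits.entries) == len(report.variants)
        stored_dr = repo.read("DiagnosticReport", f"report-1-r{i}")
        assert stored_dr.body["subject"]["reference"] == f"Patient/patient-1-r{i}"
        extracted = extract_report(bundle)
        assert extracted == report
        text, html = render_summary(bundle)
        assert report.variants[0].gene_symbol in text
        assert "</html>" in html


def _rewrite_refs(node, suffix):
    if isinstance(node, dict):
        if isinstance(node.get("reference"), str) and not node["reference"].endswith(suffix):
            node["reference"] += suffix
        for v in node.values():
            _rewrite_refs(v, suffix)
    elif isinstance(node, list):
        for v in node:
            _rewrite_refs(v, suffix)


def test_worked_example_matches_published_values(example_report):
    assert example_report.subject.birth_date == "1947-04-29"
    assert example_report.subject.identifier == "12345678"
    assert example_report.subject.name == "Gildong Hong"
    assert example_report.subject.sex_code == "1"
    assert example_report.subject.ethnicity_code == "2040-4"
    v = example_report.variants[0]
    assert v.gene_hgnc_id == "HGNC:1097"
    assert v.gene_symbol == "BRAF"
    assert v.hgvs_notation == "c.1799T > A_p.V600E"
    assert v.variant_db_id == "COSM476"
    assert v.variant_effect == "Substitution (missense)"
    assert validate_report(example_report) == []


def test_worked_example_is_stable():
    assert worked_example() == worked_example()
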