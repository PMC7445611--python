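"""The worked-example report fixture.

Reproduces the published specification example: subject 12345678 /
Gildong Hong, born 1947-04-29, sex code "1" (Male), ethnicity 2040-4
(Korean); one BRAF variant (HGNC:1097) written in the report dialect
``"c.1799T > A_p.V600E"``, a missense substitution with COSMIC id COSM476.

The example row set does not print order/specimen/report metadata, a
classification string or a treatment, so the fixture completes them
synthetically: the classification uses the published example string
"Tier 1 (Pathogenic, Identified)"; the remaining completions (order ids,
specimen, BRAF-inhibitor treatment, dates) are invented so that the
fixture is fully conformant.
"""

from __future__ import annotations

from .report_builder import (
    ClassificationTriple,
    OrderInfo,
    ReportMeta,
    SequencingReport,
    SpecimenInfo,
    SubjectInfo,
    VariantRecord,
)

__all__ = ["worked_example"]


def worked_example() -> SequencingReport:
    """A fully conformant report anchored on the published example data."""
    return SequencingReport(
        subject=SubjectInfo(
            identifier="12345678",
            name="Gildong Hong",
            birth_date="1947-04-29",
            sex_code="1",
            ethnicity_code="2040-4",
        ),
        order=OrderInfo(  # synthetic completion
            order_id="ORD-2019-0001",
            order_date="2019-03-02",
            ordering_clinician="Dr. Cheolsu Kim",
            legally_authorized_orderer="Dr. Cheolsu Kim",
            performing_laboratory="SNUBH sequencing facility",
        ),
        specimen=SpecimenInfo(  # synthetic completion
            specimen_id="SPC-0001",
            sample_type="FFPE tumor tissue",
            collection_date="2019-03-01",
        ),
        report_meta=ReportMeta(  # synthetic completion
            report_id="RPT-0001",
            report_status="final",
            test_code="NGS-PANEL-v1",
            issued_date="2019-03-15",
            interpretation_summary=(
                "A clinically significant BRAF p.V600E activating mutation "
                "was identified in the tumor sample."
            ),
            assessed_condition="Malignant melanoma",
        ),
        variants=[
            VariantRecord(
                gene_hgnc_id="HGNC:1097",
                gene_symbol="BRAF",
                hgvs_notation="c.1799T > A_p.V600E",
                variant_effect="Substitution (missense)",
                variant_db_id="COSM476",
                classification=ClassificationTriple(
                    tier="Tier 1", pathogeny="Pathogenic",
                    clinical_relevance="Identified",
                ),
                genomic_source_class="somatic",   # synthetic completion below
                result_status="final",
                variant_test_code="NGS-PANEL-v1",
                variant_interpretation="Positive",
                variant_comment="Kinase domain (exon 15)",
                test_method="Targeted NGS panel",
                observation_date="2019-03-14",
            )
        ],
        recommended_treatments=["Vemurafenib"],  # synthetic completion
    )
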