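"""Seeded synthetic report generator — the test-data engine.

Emulates the feed a hospital receives from its sequencing facility:
conformant structured reports whose codes are drawn from the registry value
sets, gene names from a bundled HGNC micro-list and variant notation from a
small HGVS grammar.  With ``missingness=0`` every generated report
validates cleanly; missingness applies only to optional (research) fields
unless the invalid-fixture flag is set, in which case required fields are
knocked out to produce deliberately non-conformant reports.
"""

from __future__ import annotations

import csv
import random
from importlib import resources
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import SeqReportError
from .iso_schema import value_set
from .report_builder import (
    ClassificationTriple,
    OrderInfo,
    ReportMeta,
    SequencingReport,
    SpecimenInfo,
    SubjectInfo,
    VariantRecord,
)

__all__ = ["GeneratorConfig", "generate_reports", "gene_micro_list"]

_SAMPLE_TYPES = ["FFPE tumor tissue", "fresh-frozen tumor tissue",
                 "peripheral blood", "bone marrow aspirate"]
_LABS = ["SNUBH sequencing facility", "Macrogen clinical lab",
         "University reference laboratory"]
_EFFECTS = ["Substitution (missense)", "Substitution (nonsense)",
            "Deletion (frameshift)", "Insertion (in-frame)", "Duplication"]
_DRUGS = ["Vemurafenib", "Dabrafenib", "Trametinib", "Erlotinib", "Gefitinib",
          "Imatinib", "Crizotinib", "Olaparib", "Trastuzumab"]
_SURNAMES = ["Hong", "Kim", "Lee", "Park", "Choi", "Jung", "Kang", "Cho"]
_GIVEN = ["Gildong", "Minsu", "Jiwoo", "Seoyeon", "Hajoon", "Yuna", "Doyun"]
_PLATFORMS = ["Illumina NextSeq 550", "Illumina NovaSeq 6000", "Ion GeneStudio S5"]
_PIPELINES = ["TruSight-Tumor-pipeline", "in-house somatic pipeline"]
_CONDITIONS = ["Malignant melanoma", "Non-small cell lung cancer",
               "Colorectal adenocarcinoma", "Acute myeloid leukemia"]
_BASES = "ACGT"


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_reports: int = Field(default=1, gt=0)
    variants_per_report: tuple[int, int] = (1, 3)
    include_research_block: float = Field(default=0.5, ge=0.0, le=1.0)
    missingness: float = Field(default=0.0, ge=0.0, le=1.0)
    #: when set, missingness also knocks out required fields (invalid fixtures)
    corrupt_required: bool = False

    @model_validator(mode="after")
    def _range_ok(self) -> "GeneratorConfig":
        lo, hi = self.variants_per_report
        if not (0 <= lo <= hi):
            raise SeqReportError(
                f"invalid variants_per_report range {self.variants_per_report}"
            )
        return self


def gene_micro_list() -> list[dict[str, str]]:
    """The bundled HGNC micro-list (id, symbol, name)."""
    text = resources.files("seqreport.data").joinpath("hgnc_genes.tsv").read_text("utf-8")
    return list(csv.DictReader(text.splitlines(), delimiter="\t"))


def _hgvs(rng: random.Random) -> str:
    pos = rng.randrange(50, 5000)
    ref, alt = rng.sample(_BASES, 2)
    aa_from, aa_to = rng.sample("ARNDCQEGHILKMFPSTWYV", 2)
    aa_pos = max(1, pos // 3)
    cdna = f"c.{pos}{ref} > {alt}" if rng.random() < 0.5 else f"c.{pos}{ref}>{alt}"
    if rng.random() < 0.85:
        return f"{cdna}_p.{aa_from}{aa_pos}{aa_to}"
    return cdna


def _classification(rng: random.Random) -> ClassificationTriple:
    return ClassificationTriple(
        tier=rng.choice([c for c, _ in value_set("tier").codes]),
        pathogeny=rng.choice([c for c, _ in value_set("pathogeny").codes]),
        clinical_relevance=rng.choice(
            [c for c, _ in value_set("clinical_relevance").codes]),
    )


def _date(rng: random.Random, year_lo=2018, year_hi=2020) -> str:
    return (f"{rng.randrange(year_lo, year_hi + 1):04d}-"
            f"{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}")


def _research_block(rng: random.Random) -> dict:
    chrom = str(rng.randrange(1, 23))
    start = rng.randrange(1_000_000, 200_000_000)
    return {
        "research.sequence_type": "dna",
        "research.coordinate_system": 1,
        "research.genome_build": rng.choice(["GRCh37", "GRCh38"]),
        "research.chromosome": chrom,
        "research.reference_seq_id": f"NC_0000{int(chrom):02d}.11",
        "research.window_start": start,
        "research.window_end": start + rng.randrange(100, 10_000),
        "research.variant_start": start + rng.randrange(0, 100),
        "research.variant_end": start + rng.randrange(100, 200),
        "research.observed_allele": rng.choice(_BASES),
        "research.reference_allele": rng.choice(_BASES),
        "research.quality_score": round(rng.uniform(20.0, 60.0), 1),
        "research.read_coverage": rng.randrange(100, 2000),
        "research.repository_url": "https://repository.example.org/seq",
        "research.repository_dataset_id": f"DS-{rng.randrange(10_000):05d}",
        "research.observed_seq": "".join(rng.choice(_BASES) for _ in range(24)),
        "research.quality_control_metrics": "Q30=93.5%;uniformity=96%",
        "research.base_calling": "RTA3",
        "research.mean_target_depth": round(rng.uniform(200.0, 900.0), 1),
        "research.percent_target_covered": round(rng.uniform(95.0, 99.9), 1),
        "research.duplication_rate": round(rng.uniform(0.02, 0.25), 3),
        "research.capture_kit": "xGen-Pan-Cancer",
        "research.pipeline_version": rng.choice(_PIPELINES) + "-2.1",
        "research.variant_caller": rng.choice(["GATK Mutect2", "VarDict", "Strelka2"]),
        "research.sequencing_platform": rng.choice(_PLATFORMS),
        "research.analysis_platform": "in-house analysis portal",
        "research.condition_under_study": rng.choice(_CONDITIONS),
        "research.allele_frequency": round(rng.uniform(0.05, 0.6), 3),
        "research.sequencer_manufacturer": "Illumina",
    }


def _one_report(rng: random.Random, cfg: GeneratorConfig, idx: int) -> SequencingReport:
    genes = gene_micro_list()
    lo, hi = cfg.variants_per_report
    n_var = rng.randrange(lo, hi + 1)
    variants = []
    for _ in range(n_var):
        g = rng.choice(genes)
        variants.append(VariantRecord(
            gene_hgnc_id=g["hgnc_id"], gene_symbol=g["symbol"],
            hgvs_notation=_hgvs(rng),
            variant_effect=rng.choice(_EFFECTS),
            variant_db_id=f"COSM{rng.randrange(100, 99_999)}",
            classification=_classification(rng),
            genomic_source_class=rng.choice(["somatic", "germline"]),
            result_status="final",
            variant_test_code="NGS-PANEL-v1",
            variant_interpretation=rng.choice(["Positive", "Negative", "Inconclusive"]),
            variant_comment=f"exon {rng.randrange(1, 30)}",
            test_method="Targeted NGS panel",
            observation_date=_date(rng),
        ))
    report = SequencingReport(
        subject=SubjectInfo(
            identifier=f"{rng.randrange(10_000_000, 99_999_999)}",
            name=f"{rng.choice(_GIVEN)} {rng.choice(_SURNAMES)}",
            birth_date=_date(rng, 1930, 1995),
            sex_code=rng.choice(["1", "2"]),
            ethnicity_code=rng.choice([c for c, _ in value_set("hl7_race").codes]),
        ),
        order=OrderInfo(
            order_id=f"ORD-{cfg.seed}-{idx:04d}",
            order_date=_date(rng),
            ordering_clinician=f"Dr. {rng.choice(_GIVEN)} {rng.choice(_SURNAMES)}",
            legally_authorized_orderer=f"Dr. {rng.choice(_GIVEN)} {rng.choice(_SURNAMES)}",
            performing_laboratory=rng.choice(_LABS),
        ),
        specimen=SpecimenInfo(
            specimen_id=f"SPC-{idx:04d}",
            sample_type=rng.choice(_SAMPLE_TYPES),
            collection_date=_date(rng),
        ),
        report_meta=ReportMeta(
            report_id=f"RPT-{cfg.seed}-{idx:04d}",
            report_status="final",
            test_code="NGS-PANEL-v1",
            issued_date=_date(rng),
            interpretation_summary=(
                f"{len(variants)} reportable variant(s) identified by targeted "
                "panel sequencing."
            ),
            assessed_condition=rng.choice(_CONDITIONS),
        ),
        variants=variants,
        recommended_treatments=rng.sample(_DRUGS, rng.randrange(1, 3)),
        research=(_research_block(rng)
                  if rng.random() < cfg.include_research_block else {}),
        no_variants_reported=(n_var == 0),
    )
    return _apply_missingness(rng, cfg, report)


def _apply_missingness(rng: random.Random, cfg: GeneratorConfig,
                       report: SequencingReport) -> SequencingReport:
    if cfg.missingness > 0 and report.research:
        report.research = {k: v for k, v in report.research.items()
                           if rng.random() >= cfg.missingness}
    if cfg.corrupt_required:
        # knock out at least one required field per report
        victims = ["subject", "order", "specimen", "report_meta"]
        victim = rng.choice(victims)
        setattr(report, victim, None)
    return report


def generate_reports(config: GeneratorConfig) -> list[SequencingReport]:
    """Deterministic corpus: same seed and config, same reports."""
    rng = random.Random(config.seed)
    return [_one_report(rng, config, i) for i in range(config.n_reports)]
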