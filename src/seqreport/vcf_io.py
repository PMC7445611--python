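"""VCF ingestion shim.

Bridges variant-caller output to report variant records: each VCF record is
joined on (CHROM, POS, REF, ALT) against an annotation sidecar table that
supplies the clinical content a raw VCF lacks — HGNC gene id/symbol, HGVS
notation in the report dialect, effect, variant-database id and the
classification string.  Records without a sidecar match are returned
separately, never dropped silently.

The sidecar is a TSV with header columns:
``chrom  pos  ref  alt  hgnc_id  symbol  notation  effect  db_id  classification``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

import pysam

from .errors import VcfError
from .report_builder import VariantRecord, parse_classification

__all__ = ["vcf_to_variants", "read_sidecar"]

SIDECAR_COLUMNS = ("chrom", "pos", "ref", "alt", "hgnc_id", "symbol",
                   "notation", "effect", "db_id", "classification")


def read_sidecar(path: Union[str, Path]) -> dict[tuple[str, int, str, str], dict]:
    """Parse the annotation sidecar keyed by (chrom, pos, ref, alt)."""
    out: dict[tuple[str, int, str, str], dict] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(SIDECAR_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise VcfError(f"sidecar lacks column(s): {sorted(missing)}")
        for lineno, rec in enumerate(reader, start=2):
            try:
                key = (rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"])
            except (TypeError, ValueError):
                raise VcfError(f"sidecar line {lineno}: bad position") from None
            out[key] = rec
    return out


def _structural_prescan(path: Union[str, Path]) -> None:
    """Cheap shape check so malformed files fail with a line number."""
    saw_fileformat = saw_header = False
    with open(path, encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1:
                saw_fileformat = line.startswith("##fileformat=VCF")
                if not saw_fileformat:
                    raise VcfError(f"line 1: missing ##fileformat header")
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not saw_header:
                raise VcfError(f"line {lineno}: data before #CHROM header line")
            if len(line.split("\t")) < 8:
                raise VcfError(f"line {lineno}: fewer than 8 tab-separated fields")
    if not saw_header:
        raise VcfError("truncated VCF: no #CHROM header line")


def vcf_to_variants(vcf_path: Union[str, Path],
                    sidecar_path: Union[str, Path],
                    ) -> tuple[list[VariantRecord], list[str]]:
    """Join a VCF with its annotation sidecar.

    Returns (variant records, unmatched record keys).
    """
    _structural_prescan(vcf_path)
    annotations = read_sidecar(sidecar_path)
    variants: list[VariantRecord] = []
    unmatched: list[str] = []
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise VcfError(f"unreadable VCF {vcf_path}: {exc}") from exc
    with vf:
        for rec in vf:
            for alt in rec.alts or ():
                key = (rec.chrom, rec.pos, rec.ref, alt)
                ann = annotations.get(key)
                if ann is None:
                    unmatched.append(f"{rec.chrom}:{rec.pos}:{rec.ref}>{alt}")
                    continue
                variants.append(VariantRecord(
                    gene_hgnc_id=ann["hgnc_id"],
                    gene_symbol=ann["symbol"],
                    hgvs_notation=ann["notation"],
                    variant_effect=ann["effect"] or None,
                    variant_db_id=ann["db_id"] or None,
                    classification=(parse_classification(ann["classification"])
                                    if ann["classification"] else None),
                ))
    return variants, unmatched
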