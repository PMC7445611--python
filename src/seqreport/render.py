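"""Clinician-facing summary renderer.

Reconstructs a report from a bundle and renders the three sections the
clinical interface presents — the variant results of the test, the
interpretation summary, and information about the test — as plain text and
as a standalone HTML page.  Output is deterministic for a given bundle.
Variant notation is shown in its raw display form.
"""

from __future__ import annotations

import html as _html

from .errors import ExtractionError
from .fhir_model import Bundle
from .report_builder import SequencingReport, extract_report, format_classification

__all__ = ["render_summary", "render_text", "render_html"]

_NO_VARIANTS = "No reportable variants were identified."

_VARIANT_COLUMNS = ("Gene", "Variant", "Effect", "Variant ID", "Classification")


def _variant_rows(report: SequencingReport) -> list[tuple[str, ...]]:
    rows = []
    for v in report.variants:
        rows.append((
            v.gene_symbol,
            v.hgvs_notation,
            v.variant_effect or "",
            v.variant_db_id or "",
            format_classification(v.classification) if v.classification else "",
        ))
    return rows


def _test_info(report: SequencingReport) -> list[tuple[str, str]]:
    rm = report.report_meta
    order = report.order
    spec = report.specimen
    subj = report.subject
    info = [
        ("Patient", f"{subj.name} ({subj.identifier})" if subj else ""),
        ("Report ID", rm.report_id if rm else ""),
        ("Test code", rm.test_code if rm else ""),
        ("Performing laboratory", order.performing_laboratory if order else ""),
        ("Specimen", spec.sample_type if spec else ""),
        ("Issued", rm.issued_date if rm else ""),
    ]
    return [(k, v or "") for k, v in info]


def render_text(bundle: Bundle) -> str:
    try:
        report = extract_report(bundle)
    except ExtractionError:
        raise
    lines = ["=== Variant results ==="]
    rows = _variant_rows(report)
    if rows:
        lines.append("\t".join(_VARIANT_COLUMNS))
        lines += ["\t".join(r) for r in rows]
    else:
        lines.append(_NO_VARIANTS)
    lines.append("")
    lines.append("=== Interpretation summary ===")
    summary = report.report_meta.interpretation_summary if report.report_meta else None
    lines.append(summary or "(no summary provided)")
    if report.recommended_treatments:
        lines.append("Recommended treatments: "
                     + ", ".join(report.recommended_treatments))
    lines.append("")
    lines.append("=== Test information ===")
    lines += [f"{k}: {v}" for k, v in _test_info(report)]
    return "\n".join(lines) + "\n"


def render_html(bundle: Bundle) -> str:
    report = extract_report(bundle)
    esc = _html.escape
    parts = ["<!DOCTYPE html>", "<html><head><meta charset='utf-8'>",
             "<title>Clinical sequencing report</title></head><body>"]
    parts.append("<h2>Variant results</h2>")
    rows = _variant_rows(report)
    if rows:
        parts.append("<table border='1'><tr>"
                     + "".join(f"<th>{esc(c)}</th>" for c in _VARIANT_COLUMNS)
                     + "</tr>")
        for r in rows:
            parts.append("<tr>" + "".join(f"<td>{esc(c)}</td>" for c in r) + "</tr>")
        parts.append("</table>")
    else:
        parts.append(f"<p>{esc(_NO_VARIANTS)}</p>")
    parts.append("<h2>Interpretation summary</h2>")
    summary = report.report_meta.interpretation_summary if report.report_meta else None
    parts.append(f"<p>{esc(summary or '(no summary provided)')}</p>")
    if report.recommended_treatments:
        parts.append("<p>Recommended treatments: "
                     + esc(", ".join(report.recommended_treatments)) + "</p>")
    parts.append("<h2>Test information</h2><dl>")
    for k, v in _test_info(report):
        parts.append(f"<dt>{esc(k)}</dt><dd>{esc(v)}</dd>")
    parts.append("</dl></body></html>")
    return "\n".join(parts) + "\n"


def render_summary(bundle: Bundle) -> tuple[str, str]:
    """(plain text, HTML) clinician summary of a report bundle."""
    return render_text(bundle), render_html(bundle)
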