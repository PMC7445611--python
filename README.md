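# seqreport

Structured clinical genomic sequencing reports as validated, machine-processable
FHIR bundles.

Most hospitals still hand clinicians NGS panel results as PDFs or free text.
`seqreport` implements the alternative: the standardized structured report
template for clinical genomic sequencing in EHRs — 32 *required* data elements
(subject of care, sequencing order, performing laboratory, biomaterial, genetic
variation, recommended treatments) and 29 *optional* research elements
(alignment coordinates, QC metrics, base calling, sequencing and analysis
platforms) — together with its bidirectional mapping onto HL7 FHIR STU3
Genomics resources. It is aimed at clinical-informatics engineers who need to
produce, exchange, validate and render sequencing-report content without PDFs.

The core artifacts are:

- an **element registry** with terminology bindings (HGNC, HGVS, ISO 8601,
  subject-identification sex coding, HL7 v3 race codes) and controlled value
  sets — the pathogenicity set (`Pathogenic` … `Benign`, 5 codes) and the
  clinical-relevance set (`Identified` … `Not identified`, 4 codes);
- a **mapping table** of 90 mapped FHIR element slots over 8 resource types
  (required fields: 26 reused core elements + 15 extensions across
  ProcedureRequest, DiagnosticReport, Observation, Medication, Patient;
  optional fields: 28 reused + 21 extensions across Condition,
  DiagnosticReport, MolecularSequence, Observation, Device), with extension
  definitions such as `Observation.extension(observation-geneticsGene)` and
  the classification triple
  `observation-classificationVariants.{Tier, Pathogeny, ClinicalRelavance}`
  that decomposes strings like `"Tier 1 (Pathogenic, Identified)"`;
- a **bundle builder / extractor** (`build_bundle` / `extract_report`) that is
  an exact round trip on conformant reports, plus conformance **validation**
  and a Table-style coverage audit;
- an in-memory FHIR-style **repository** (create, read, update, history,
  search) with an optional stdlib HTTP facade and a token-table authorization
  stub;
- a seeded **synthetic report generator**, a VCF + annotation-sidecar
  ingestion shim, and a clinician summary **renderer** (text and HTML).

## Worked example

The package ships the published specification example — subject `12345678`
"Gildong Hong" (born 1947-04-29, sex code `1`/Male, ethnicity `2040-4`
Korean) with a somatic BRAF variant written in the report dialect
`"c.1799T > A_p.V600E"`, COSMIC id `COSM476`, classified
`"Tier 1 (Pathogenic, Identified)"`:

```sh
$ seqreport worked-example -o report.json
$ seqreport validate report.json
conformant: no issues
$ seqreport build report.json -o bundle.json
$ seqreport render bundle.json
=== Variant results ===
Gene    Variant                 Effect                   Variant ID  Classification
BRAF    c.1799T > A_p.V600E     Substitution (missense)  COSM476     Tier 1 (Pathogenic, Identified)

=== Interpretation summary ===
A clinically significant BRAF p.V600E activating mutation was identified in the tumor sample.
Recommended treatments: Vemurafenib

=== Test information ===
Patient: Gildong Hong (12345678)
...
```

The variant notation is parsed into normalized HGVS (`c.1799T>A`, `p.V600E`)
while the raw display form is preserved; `seqreport extract bundle.json`
reproduces `report.json` exactly.

`seqreport stats` prints the per-resource slot count table (26+15 required,
28+21 optional, 90 total); `seqreport registry export` emits the element
registry (32 required / 29 optional rows) as CSV or JSON;
`seqreport generate --seed 7 --n 10 -o corpus/` writes a deterministic
synthetic corpus; `seqreport serve` runs the HTTP repository facade.

## Layout

```
src/seqreport/
  iso_schema.py      element registry and value sets
  mapping.py         element → FHIR slot table, extension definitions
  fhir_model.py      generic STU3-dialect resources, bundles, JSON
  report_builder.py  report model, grammars, build/extract round trip
  validation.py      conformance checks and coverage audit
  repository.py      in-memory FHIR-style store
  generator.py       seeded synthetic report corpus
  fixtures.py        the worked-example report
  vcf_io.py          VCF + sidecar → variant records
  render.py          clinician summary (text/HTML)
  http_facade.py     stdlib REST adapter over the repository
  cli.py             the `seqreport` command
  data/              registry, mapping, extensions, value sets, gene micro-list
```

See `docs/methods.md` for the data model, design decisions and limitations.
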