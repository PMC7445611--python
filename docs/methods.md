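# Methods

## The data model

The package models a structured clinical genomic sequencing report as a
fixed registry of 61 data elements split into two field classes: 32
**required** elements covering the clinically actionable core (clinical
sequencing order information, subject of care, biomaterial, test
information, genetic variation, recommended treatments) and 29 **optional**
elements aimed at clinical research (sequence/alignment coordinates on a
reference assembly, quality-control and pipeline metadata, research
context). Each element carries exactly one metadata binding that says how
its value is written:

| binding | applies to | check performed |
|---|---|---|
| ISO/TS 22220:2011 | subject identifier, name, sex | sex code in the 0/1/2/9 table |
| ISO 8601 | all dates | `datetime.fromisoformat` must accept the string |
| HL7 v3 race | ethnicity | lexical shape `<digits>-<digit>` |
| HGNC | gene | id matches `HGNC:<digits>` |
| HGVS | variant notation | `c.`/`g.` prefix (no reference-sequence semantics) |
| database-ID | variant/external ids | free string |
| text / none | everything else | none (warnings only) |

Element identity is a dot-path (`subject.birth_date`,
`genetic_variation.gene_symbol`, `research.base_calling`). Elements whose
names are directly attested by the source template ship with
`provenance="paper"`; the remainder — the full normative element list is
not freely redistributable — are reconstructed under the correct sections
with plausible names and flagged `provenance="reconstructed"`. The
reconstruction is constrained so that **every published cardinality
holds**: 32/29 elements, and the per-resource slot counts below.

## Elements vs. mapped slots (61 → 90)

The FHIR mapping is stored as one row per *mapped FHIR element slot*, not
per element. A single element may legitimately occupy several slots:

* the variant classification expands into three sub-extensions
  (`observation-classificationVariants.{Tier, Pathogeny, ClinicalRelavance}`
  — the last name kept with its historical spelling);
* subject demographics appear both through the report's
  `DiagnosticReport.subject(patient)` dereference and on the Patient
  resource itself;
* a recommended treatment is a free-standing Medication entry *and* a
  reference-valued extension on the DiagnosticReport;
* research metadata is stored on MolecularSequence and mirrored where it is
  clinically surfaced (variant Observation components/extensions, Device,
  DiagnosticReport).

This is the only accounting under which the published totals are all
simultaneously true: 41 required slots (26 reused core elements + 15
extensions over ProcedureRequest 3+0, DiagnosticReport 12+5, Observation
8+8, Medication 1+0, Patient 2+2) and 49 optional slots (28+21 over
Condition 1+0, DiagnosticReport 2+2, MolecularSequence 16+10, Observation
6+6, Device 3+3), 90 slots in total. `map_element` returns the element's
*primary* slot (first in table order, its home resource);
`rows_for_element` returns all of them.

Each slot stores two path forms: the display path in the source dialect
(`Observation.extension(observation-geneticsGene)`,
`DiagnosticReport.subject(patient)`) and a machine `placement` — a
slash-separated structural path with dict keys, list indices, `ext:NAME`
extension steps, a `@Patient` reference dereference and `component{code}`
selection. The builder writes through placements; the coverage audit and
the test-suite's independent brute-force walker read through them.

## FHIR dialect

Resources are generic STU3-dialect JSON objects (the eight mapped types
plus Bundle); there is no full FHIR metamodel, no XML/RDF, no FHIRPath and
no StructureDefinition validation (a JSON stub per extension definition is
provided instead). Extension URLs live under a package-owned canonical
namespace (`https://seqreport.example.org/fhir/StructureDefinition/`) since
the source names extensions but not URLs; sub-extension URLs are relative
names, as FHIR prescribes. The resource-type name `ProcedureRequest` is
canonical (matching the published counts); `ServiceRequest` is accepted as
an input alias, as is `Sequence` for `MolecularSequence`. Some complex
STU3 datatypes are simplified to scalars where the report only ever carries
one value (e.g. `referenceSeq.chromosome` holds the chromosome string
rather than a CodeableConcept). Canonical JSON output is UTF-8 with sorted
keys, two-space indent and a trailing newline, so serialized fixtures are
byte-stable; `from_json ∘ to_json` is the identity.

Sex coding: the template fixes only `"1" → Male`. The package completes
the table with the common 0/1/2/9 layout (`0` not known, `2` female, `9`
not applicable). The DR-dereferenced slot stores the translated FHIR-style
gender token; the raw code rides the `patient-sexCode` extension, which is
also where extraction reads it back.

## Grammars

* **Classification**: `"<Tier> (<Pathogeny>, <ClinicalRelevance>)"`,
  whitespace-tolerant, each component validated against its value set
  (tiers `Tier 1`–`Tier 4`; the template shows only `Tier 1`, the four-tier
  somatic convention completes the set). `parse` and `format` are mutual
  inverses on canonical forms.
* **Variant notation**: `"<cdna>_<protein>"` with optional protein part and
  spaces tolerated around `>`. The raw string is preserved verbatim for
  display; normalized HGVS (`c.1799T>A`, `p.V600E`) is derived and stored.
  No reference-sequence validation, left-shifting or transcript resolution
  is attempted.

## Build / extract round trip

`build_bundle` refuses any report with error-severity validation findings
(validation is exactly the builder's gate). It emits a collection bundle
with deterministic logical ids: one Patient, one ProcedureRequest, one
DiagnosticReport (whose `result` references one Observation per variant),
one Medication per recommended treatment, and — only when research fields
are present — MolecularSequence/Device/Condition entries. Research values
that surface on Observations are placed on the first variant Observation.
`extract_report` inverts the builder on its image; unknown extensions are
collected into an `unmapped` side list (via `extract_report_detailed`),
never dropped silently.

A report with an empty variant list is only conformant when the explicit
negative-result flag `no_variants_reported` is set; with the flag off, all
12 per-variant required elements count as missing, so a default-constructed
empty report yields exactly 32 missing-required findings. Research values
whose only slots sit on Observations cannot round-trip through a
zero-variant bundle; the generator never produces that combination.

## Synthetic generator

The generator emulates the sequencing facility's feed: per report 1–3
somatic variants by default, genes drawn from a bundled 20-gene HGNC
micro-list (BRAF, EGFR, KRAS, TP53, …), HGVS strings from a small
substitution grammar (85 % with a protein part, a mix of spaced and
unspaced `>` forms), classification codes drawn uniformly from the value
sets, Korean-style demographics, 2018–2020 ISO dates, and a research block
attached with probability 0.5 by default (read coverage 100–2000×, mean
target depth 200–900×, allele fractions 0.05–0.6 — typical targeted-panel
magnitudes). `missingness` thins only optional fields; a separate
`corrupt_required` flag produces deliberately non-conformant fixtures.
Everything derives from one `random.Random(seed)`, so equal seed + config
gives an identical corpus.

What it does **not** emulate: correlated missingness, real variant/disease
co-occurrence, genuine HGVS complexity (indels, splice, structural
variants), multi-sample reports, or free-text noise. Passing round-trip
and conformance suites on this corpus therefore demonstrates structural
correctness of the mapping and builder, not robustness to messy real-world
laboratory feeds.

## Repository and facade

The repository is an in-memory store with per-resource version chains
(update increments the version by exactly 1; history is append-only,
oldest first), AND-semantics search over a deliberately small parameter set
(`subject`, `gene`, `date`-prefix) checked against a brute-force scan in
tests, and an optional JSON-lines snapshot. Delete exists only as a
soft-delete behind a constructor switch, reconciling the two operation
lists the source gives (repository build vs. server support). Access
control is a deterministic token→operations table standing in for
bearer-token authorization; it is off unless tokens are configured. The
HTTP facade is a thin stdlib `http.server` adapter; the library API is the
contract.

## Numerical/size choices

The acceptance script uses 200 synthetic reports for the round-trip rate,
one fully populated report for the 90-slot coverage audit and 100 stored
resources / 25 queries for search-vs-scan agreement — sizes at which every
quantity is already exact and the whole script runs in ~1 s. All
randomness is seeded from the CLI `--seed` (sub-seeds reduced mod 2³¹).

## Known limitations

* Reconstructed element names are plausible, not normative; only counts,
  sections and the attested rows are guaranteed.
* Terminology checks are lexical/offline; no terminology-server lookups,
  SNOMED/LOINC coverage or semantic HGVS validation.
* One report maps to one Patient/DiagnosticReport; multi-report subjects
  are only supported at the repository layer.
* The HTTP facade implements exactly the five supported operations — no
  paging, search modifiers, chaining or conditional operations.
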