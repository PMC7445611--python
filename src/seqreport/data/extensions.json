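[
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/patient-ethnicity",
  "name": "patient-ethnicity",
  "value_type": "code",
  "host_resource": "Patient"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/patient-sexCode",
  "name": "patient-sexCode",
  "value_type": "code",
  "host_resource": "Patient"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/diagnosticReport-legallyAuthorizedRepresentative",
  "name": "diagnosticReport-legallyAuthorizedRepresentative",
  "value_type": "string",
  "host_resource": "DiagnosticReport"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/diagnosticReport-geneticsAssessedCondition",
  "name": "diagnosticReport-geneticsAssessedCondition",
  "value_type": "string",
  "host_resource": "DiagnosticReport"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/diagnosticReport-recommendedTreatment",
  "name": "diagnosticReport-recommendedTreatment",
  "value_type": "reference",
  "host_resource": "DiagnosticReport"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/diagnosticReport-specimenCollectionDate",
  "name": "diagnosticReport-specimenCollectionDate",
  "value_type": "string",
  "host_resource": "DiagnosticReport"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-geneticsGene",
  "name": "observation-geneticsGene",
  "value_type": "codeable-concept",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-geneticsDNASequenceVariantName",
  "name": "observation-geneticsDNASequenceVariantName",
  "value_type": "string",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-geneticsDNASequenceVariantType",
  "name": "observation-geneticsDNASequenceVariantType",
  "value_type": "string",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-geneticsDNAVariantId",
  "name": "observation-geneticsDNAVariantId",
  "value_type": "identifier",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-geneticsGenomicSourceClass",
  "name": "observation-geneticsGenomicSourceClass",
  "value_type": "code",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-classificationVariants.Tier",
  "name": "observation-classificationVariants.Tier",
  "value_type": "string",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-classificationVariants.Pathogeny",
  "name": "observation-classificationVariants.Pathogeny",
  "value_type": "string",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-classificationVariants.ClinicalRelavance",
  "name": "observation-classificationVariants.ClinicalRelavance",
  "value_type": "string",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/sequence-qualityControlMetrics",
  "name": "sequence-qualityControlMetrics",
  "value_type": "string",
  "host_resource": "MolecularSequence"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/sequence-baseCalling",
  "name": "sequence-baseCalling",
  "value_type": "string",
  "host_resource": "MolecularSequence"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/sequence-meanTargetDepth",
  "name": "sequence-meanTargetDepth",
  "value_type": "quantity",
  "host_resource": "MolecularSequence"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/sequence-percentTargetCovered",
  "name": "sequence-percentTargetCovered",
  "value_type": "quantity",
  "host_resource": "MolecularSequence"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/sequence-duplicationRate",
  "name": "sequence-duplicationRate",
  "value_type": "quantity",
  "host_resource": "MolecularSequence"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/sequence-captureKit",
  "name": "sequence-captureKit",
  "value_type": "string",
  "host_resource": "MolecularSequence"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/sequence-pipelineVersion",
  "name": "sequence-pipelineVersion",
  "value_type": "string",
  "host_resource": "MolecularSequence"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/sequence-variantCaller",
  "name": "sequence-variantCaller",
  "value_type": "string",
  "host_resource": "MolecularSequence"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/sequence-sequencingPlatform",
  "name": "sequence-sequencingPlatform",
  "value_type": "string",
  "host_resource": "MolecularSequence"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/sequence-analysisPlatform",
  "name": "sequence-analysisPlatform",
  "value_type": "string",
  "host_resource": "MolecularSequence"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-geneticsGenomeBuild",
  "name": "observation-geneticsGenomeBuild",
  "value_type": "string",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-geneticsChromosome",
  "name": "observation-geneticsChromosome",
  "value_type": "string",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-geneticsRefSeq",
  "name": "observation-geneticsRefSeq",
  "value_type": "string",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-coordinateSystem",
  "name": "observation-coordinateSystem",
  "value_type": "quantity",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-sequenceRepositoryUrl",
  "name": "observation-sequenceRepositoryUrl",
  "value_type": "string",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/observation-qcSummary",
  "name": "observation-qcSummary",
  "value_type": "string",
  "host_resource": "Observation"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/diagnosticReport-sequencingPlatform",
  "name": "diagnosticReport-sequencingPlatform",
  "value_type": "string",
  "host_resource": "DiagnosticReport"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/diagnosticReport-analysisPlatform",
  "name": "diagnosticReport-analysisPlatform",
  "value_type": "string",
  "host_resource": "DiagnosticReport"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/device-analysisPlatform",
  "name": "device-analysisPlatform",
  "value_type": "string",
  "host_resource": "Device"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/device-captureKit",
  "name": "device-captureKit",
  "value_type": "string",
  "host_resource": "Device"
 },
 {
  "url": "https://seqreport.example.org/fhir/StructureDefinition/device-variantCaller",
  "name": "device-variantCaller",
  "value_type": "string",
  "host_resource": "Device"
 }
]
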