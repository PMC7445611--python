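{
 "pathogeny": [
  [
   "Pathogenic",
   "Pathogenic"
  ],
  [
   "Likely pathogenic",
   "Likely pathogenic"
  ],
  [
   "Unknown significance",
   "Unknown significance"
  ],
  [
   "Likely benign",
   "Likely benign"
  ],
  [
   "Benign",
   "Benign"
  ]
 ],
 "clinical_relevance": [
  [
   "Identified",
   "Identified"
  ],
  [
   "Likely identified",
   "Likely identified"
  ],
  [
   "Uncertain",
   "Uncertain"
  ],
  [
   "Not identified",
   "Not identified"
  ]
 ],
 "tier": [
  [
   "Tier 1",
   "Tier 1"
  ],
  [
   "Tier 2",
   "Tier 2"
  ],
  [
   "Tier 3",
   "Tier 3"
  ],
  [
   "Tier 4",
   "Tier 4"
  ]
 ],
 "sex_iso22220": [
  [
   "0",
   "Not known"
  ],
  [
   "1",
   "Male"
  ],
  [
   "2",
   "Female"
  ],
  [
   "9",
   "Not applicable"
  ]
 ],
 "hl7_race": [
  [
   "2040-4",
   "Korean"
  ],
  [
   "2028-9",
   "Asian"
  ],
  [
   "2106-3",
   "White"
  ],
  [
   "2054-5",
   "Black or African American"
  ]
 ],
 "genomic_source_class": [
  [
   "somatic",
   "Somatic"
  ],
  [
   "germline",
   "Germline"
  ]
 ]
}
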