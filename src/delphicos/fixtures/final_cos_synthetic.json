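{
 "synthetic": true,
 "note": "Final five-outcome COS membership reconstructed from the congruency statements (all five in the 5-point preliminary COS, four of five in the 9-point; none interview-derived; none patient-suggested). The source study does not itemise the final list.",
 "outcomes": [
  "pain_frequency",
  "pain_intensity_severity",
  "function_disability_activity_limitation",
  "health_related_quality_of_life",
  "fear_avoidance"
 ]
}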