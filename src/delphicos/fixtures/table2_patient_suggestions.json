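[
 {
  "raw_text": "Alternative therapy - impact and access to - some medications cannot be used",
  "decision": "not_an_outcome",
  "note": "covered by the definition of healthcare utilisation"
 },
 {
  "raw_text": "Likelihood of planning subsequent pregnancies, due to risk of reoccurrence",
  "decision": "include_new",
  "new_outcome_id": "likelihood_subsequent_pregnancies",
  "new_outcome_name": "Likelihood of planning subsequent pregnancies"
 },
 {
  "raw_text": "Onset of PGP: pregnancy week or postpartum",
  "decision": "not_an_outcome"
 },
 {
  "raw_text": "Maternal comorbidities such as Ehlers-Danlos or diabetic. Family related PGP",
  "decision": "not_an_outcome",
  "note": "risk factor"
 },
 {
  "raw_text": "In ability to bond with child, relationship damage",
  "decision": "already_included",
  "mapped_outcome_id": "family_life_impact"
 },
 {
  "raw_text": "Information on lactation for how long, problems, in which positions",
  "decision": "already_included",
  "mapped_outcome_id": "function_disability_activity_limitation"
 },
 {
  "raw_text": "Menstruation when returned after birth and what about PGP in connection with menstruation",
  "decision": "include_new",
  "new_outcome_id": "symptoms_during_menstruation",
  "new_outcome_name": "Symptoms during menstruation"
 },
 {
  "raw_text": "Postnatal experiences of PGP",
  "decision": "not_an_outcome"
 },
 {
  "raw_text": "Length of time to become pain free again",
  "decision": "already_included",
  "mapped_outcome_id": "recovery_of_symptoms"
 },
 {
  "raw_text": "Mattress - what quality, need of overlay that reduce pressure on the pelvic joints",
  "decision": "include_new",
  "new_outcome_id": "need_for_additional_supports",
  "new_outcome_name": "Needs for additional supports"
 },
 {
  "raw_text": "Need for help with taking care of the baby, need of daycare for older siblings",
  "decision": "already_included",
  "mapped_outcome_id": "dependence_on_others"
 },
 {
  "raw_text": "Need for help with the daily work in the house like making dinner, cleaning, washing clothes",
  "decision": "already_included",
  "mapped_outcome_id": "function_disability_activity_limitation"
 },
 {
  "raw_text": "Perseverance in standing",
  "decision": "already_included",
  "mapped_outcome_id": "function_disability_activity_limitation"
 },
 {
  "raw_text": "Accessibility of treatment",
  "decision": "not_an_outcome"
 },
 {
  "raw_text": "How your own hormones affects the ability to do things, and how it affects the pain",
  "decision": "not_an_outcome"
 },
 {
  "raw_text": "Fitness levels prior to pain onset",
  "decision": "already_included",
  "mapped_outcome_id": "physical_activity_levels"
 },
 {
  "raw_text": "How long the PGP pain has lasted",
  "decision": "include_new",
  "new_outcome_id": "pain_duration",
  "new_outcome_name": "Pain duration/pain pattern"
 }
]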