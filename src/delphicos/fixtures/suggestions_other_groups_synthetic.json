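[
 {
  "raw_text": "[synthetic reconstruction] Breathing function",
  "decision": "include_new",
  "new_outcome_id": "breathing_function",
  "new_outcome_name": "Breathing function"
 },
 {
  "raw_text": "[synthetic reconstruction] Clinical findings on motion palpation/joint play of pelvic girdle joints",
  "decision": "include_new",
  "new_outcome_id": "motion_palpation_findings",
  "new_outcome_name": "Clinical findings on motion palpation/joint play of pelvic girdle joints"
 },
 {
  "raw_text": "[synthetic reconstruction] Coping strategies/coping styles",
  "decision": "include_new",
  "new_outcome_id": "coping_strategies",
  "new_outcome_name": "Coping strategies/coping styles"
 },
 {
  "raw_text": "[synthetic reconstruction] Global perceived improvement/global rate of change",
  "decision": "include_new",
  "new_outcome_id": "global_perceived_improvement",
  "new_outcome_name": "Global perceived improvement/global rate of change"
 },
 {
  "raw_text": "[synthetic reconstruction] Goal attainment",
  "decision": "include_new",
  "new_outcome_id": "goal_attainment",
  "new_outcome_name": "Goal attainment"
 },
 {
  "raw_text": "[synthetic reconstruction] Motor control/movement strategies/movement patterns",
  "decision": "include_new",
  "new_outcome_id": "motor_control",
  "new_outcome_name": "Motor control/movement strategies/movement patterns"
 },
 {
  "raw_text": "[synthetic reconstruction] Muscle tightness",
  "decision": "include_new",
  "new_outcome_id": "muscle_tightness",
  "new_outcome_name": "Muscle tightness"
 },
 {
  "raw_text": "[synthetic reconstruction] Outcomes from functional tests",
  "decision": "include_new",
  "new_outcome_id": "functional_test_outcomes",
  "new_outcome_name": "Outcomes from functional tests"
 },
 {
  "raw_text": "[synthetic reconstruction] Patients beliefs about pain/meaning of complaints to patient",
  "decision": "include_new",
  "new_outcome_id": "patient_beliefs_about_pain",
  "new_outcome_name": "Patients beliefs about pain/meaning of complaints to patient"
 },
 {
  "raw_text": "[synthetic reconstruction] Patient understanding/knowledge of PGP",
  "decision": "include_new",
  "new_outcome_id": "patient_understanding_of_pgp",
  "new_outcome_name": "Patient understanding/knowledge of PGP"
 },
 {
  "raw_text": "[synthetic reconstruction] Postural observation",
  "decision": "include_new",
  "new_outcome_id": "postural_observation",
  "new_outcome_name": "Postural observation"
 }
]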