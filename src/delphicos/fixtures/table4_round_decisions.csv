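outcome_id,name,sources,first_round,r1_5pt,r1_9pt,r2_5pt,r2_9pt,r3_5pt,r3_9pt
pain_behaviour,Pain behaviour,systematic_review,1,in,out,out,out,not_rated,not_rated
pain_character_type,Pain character/type,interview,1,in,out,in,in,out,out
pain_frequency,Pain frequency,systematic_review,1,in,in,in,in,in,in
pain_intensity_severity,Pain intensity/severity,systematic_review,1,in,in,in,in,in,in
pain_location,Pain location,systematic_review,1,in,in,in,in,in,in
full_pain_recovery,Full pain recovery,systematic_review,1,in,in,in,in,in,out
function_disability_activity_limitation,Function/disability/activity limitation,systematic_review,1,in,in,in,in,in,in
physical_activity_levels,Physical activity levels/exercise limitations,systematic_review,1,in,in,in,in,in,in
need_for_mobility_aid,Need for mobility aid,interview,1,in,out,in,out,out,not_rated
perceived_body_imbalance,Perceived body imbalance,interview,1,out,out,out,out,not_rated,not_rated
sexual_functioning,Sexual functioning,interview,1,in,out,in,out,in,not_rated
health_related_quality_of_life,Health related quality of life,systematic_review,1,in,in,in,in,in,in
health_status,Health status,systematic_review,1,in,in,in,in,in,out
family_life_impact,Family life impact,interview,1,in,in,in,in,in,out
social_life_impact,Social life impact,interview,1,in,in,in,in,in,out
patient_satisfaction_with_life,Patient satisfaction with life,systematic_review,1,in,in,in,in,in,out
patient_satisfaction_with_treatment,Patient satisfaction with treatment,systematic_review,1,in,in,in,in,in,in
patient_expectations_of_treatment,Patient expectations of treatment,systematic_review,1,in,in,out,in,not_rated,in
anxiety,Anxiety,systematic_review,1,in,in,in,in,in,out
confidence,Confidence,systematic_review,1,in,in,out,out,not_rated,not_rated
depression,Depression,systematic_review,1,in,in,in,out,out,not_rated
dependence_on_others,Dependence on others,systematic_review,1,in,in,out,out,not_rated,not_rated
emotional_symptoms,Emotional symptoms,interview,1,in,in,in,out,in,not_rated
fear_avoidance,Fear avoidance,systematic_review,1,in,in,in,in,in,out
frustration,Frustration,interview,1,out,out,out,out,not_rated,not_rated
pain_catastrophizing,Pain catastrophizing,systematic_review,1,in,in,in,out,in,not_rated
self_efficacy,Self-efficacy,systematic_review,1,in,in,in,out,out,not_rated
well_being,Well-being,systematic_review,1,in,in,out,out,not_rated,not_rated
fatigue,Fatigue,systematic_review,1,in,out,out,out,not_rated,not_rated
sleep_function,Sleep function,systematic_review,1,in,in,in,in,in,out
work_ability,Work ability,systematic_review,1,in,in,in,in,in,in
work_performance,Work performance,systematic_review,1,in,in,in,out,out,not_rated
analgesia_use,Analgesia use,systematic_review,1,in,out,out,out,not_rated,not_rated
cost,Cost,systematic_review,1,in,in,out,out,not_rated,not_rated
healthcare_utilisation,Healthcare utilisation,systematic_review,1,in,in,in,out,out,not_rated
anthropomorphic_outcomes,Anthropomorphic outcomes,systematic_review,1,out,out,out,out,not_rated,not_rated
body_flexibility,Body flexibility,systematic_review,1,out,out,out,out,not_rated,not_rated
functional_mobility,Functional mobility,systematic_review,1,in,out,out,out,not_rated,not_rated
gait_endurance,Gait endurance,systematic_review,1,in,out,in,out,in,not_rated
gait_speed,Gait speed,systematic_review,1,out,out,out,out,not_rated,not_rated
newborn_outcomes,New-born outcomes,systematic_review,1,out,out,out,out,not_rated,not_rated
pain_provocation_test_outcomes,Outcomes from pain provocation/location tests,systematic_review,1,in,out,out,out,not_rated,not_rated
posture,Posture,systematic_review,1,in,out,out,out,not_rated,not_rated
pubis_symphysis_mobility,Pubis symphysis mobility,systematic_review,1,out,out,out,out,not_rated,not_rated
maternal_pregnancy_outcomes,Maternal pregnancy outcomes,systematic_review,1,out,out,out,out,not_rated,not_rated
muscle_endurance,Muscle endurance,systematic_review,1,out,out,out,out,not_rated,not_rated
muscle_strength,Muscle strength,systematic_review,1,in,out,out,out,not_rated,not_rated
recovery_of_symptoms,Recovery of symptoms,systematic_review,1,in,in,in,in,in,in
step_length,Step length,systematic_review,1,out,out,out,out,not_rated,not_rated
surgical_outcomes,Surgical outcomes,systematic_review,1,out,out,out,out,not_rated,not_rated
urinary_incontinence,Urinary incontinence,systematic_review,1,in,in,in,out,in,not_rated
maternal_adverse_outcomes,Maternal adverse outcomes/undesirable effects,systematic_review,1,in,out,in,out,out,not_rated
unborn_born_adverse_outcomes,Unborn/born adverse outcomes/undesirable effects,systematic_review,1,out,out,out,out,not_rated,not_rated
breathing_function,Breathing function,round1_suggestion,2,not_rated,not_rated,out,out,not_rated,not_rated
motion_palpation_findings,Clinical findings on motion palpation/joint play of pelvic girdle joints,round1_suggestion,2,not_rated,not_rated,out,out,not_rated,not_rated
coping_strategies,Coping strategies/coping styles,round1_suggestion,2,not_rated,not_rated,in,out,out,not_rated
global_perceived_improvement,Global perceived improvement/global rate of change,round1_suggestion,2,not_rated,not_rated,in,out,out,not_rated
goal_attainment,Goal attainment,round1_suggestion,2,not_rated,not_rated,in,out,out,not_rated
likelihood_subsequent_pregnancies,Likelihood of planning subsequent pregnancies,round1_suggestion,2,not_rated,not_rated,out,out,not_rated,not_rated
motor_control,Motor control/movement strategies/movement patterns,round1_suggestion,2,not_rated,not_rated,in,out,in,not_rated
muscle_tightness,Muscle tightness,round1_suggestion,2,not_rated,not_rated,out,out,not_rated,not_rated
need_for_additional_supports,Needs for additional supports,round1_suggestion,2,not_rated,not_rated,out,out,not_rated,not_rated
functional_test_outcomes,Outcomes from functional tests,round1_suggestion,2,not_rated,not_rated,in,out,out,not_rated
pain_duration,Pain duration/pain pattern,round1_suggestion,2,not_rated,not_rated,in,in,in,in
patient_beliefs_about_pain,Patients beliefs about pain/meaning of complaints to patient,round1_suggestion,2,not_rated,not_rated,in,out,out,not_rated
patient_understanding_of_pgp,Patient understanding/knowledge of PGP,round1_suggestion,2,not_rated,not_rated,in,out,out,not_rated
postural_observation,Postural observation,round1_suggestion,2,not_rated,not_rated,out,out,not_rated,not_rated
symptoms_during_menstruation,Symptoms during menstruation,round1_suggestion,2,not_rated,not_rated,out,out,not_rated,not_rated
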