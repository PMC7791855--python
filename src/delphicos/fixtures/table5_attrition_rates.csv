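arm,group,transition,percent
5pt,clinician,r1_to_r2,30
5pt,clinician,r2_to_r3,10
5pt,clinician,overall,37
5pt,clinician_researcher,r1_to_r2,17
5pt,clinician_researcher,r2_to_r3,0
5pt,clinician_researcher,overall,17
5pt,patient,r1_to_r2,30
5pt,patient,r2_to_r3,29
5pt,patient,overall,50
5pt,researcher,r1_to_r2,0
5pt,researcher,r2_to_r3,0
5pt,researcher,overall,0
5pt,service_provider_policy_maker,r1_to_r2,40
5pt,service_provider_policy_maker,r2_to_r3,0
5pt,service_provider_policy_maker,overall,40
5pt,overall,r1_to_r2,25
5pt,overall,r2_to_r3,9
5pt,overall,overall,32
9pt,clinician,r1_to_r2,40
9pt,clinician,r2_to_r3,14
9pt,clinician,overall,48
9pt,clinician_researcher,r1_to_r2,7
9pt,clinician_researcher,r2_to_r3,0
9pt,clinician_researcher,overall,7
9pt,patient,r1_to_r2,45
9pt,patient,r2_to_r3,33
9pt,patient,overall,64
9pt,researcher,r1_to_r2,15
9pt,researcher,r2_to_r3,0
9pt,researcher,overall,15
9pt,service_provider_policy_maker,r1_to_r2,17
9pt,service_provider_policy_maker,r2_to_r3,0
9pt,service_provider_policy_maker,overall,17
9pt,overall,r1_to_r2,32
9pt,overall,r2_to_r3,11
9pt,overall,overall,39
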