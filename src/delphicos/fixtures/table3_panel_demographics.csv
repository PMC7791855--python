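block,category,arm,round,n
stakeholder_group,clinician,5pt,1,43
stakeholder_group,clinician,9pt,1,48
stakeholder_group,clinician,5pt,2,30
stakeholder_group,clinician,9pt,2,29
stakeholder_group,clinician,5pt,3,27
stakeholder_group,clinician,9pt,3,25
stakeholder_group,clinician_researcher,5pt,1,23
stakeholder_group,clinician_researcher,9pt,1,15
stakeholder_group,clinician_researcher,5pt,2,19
stakeholder_group,clinician_researcher,9pt,2,14
stakeholder_group,clinician_researcher,5pt,3,19
stakeholder_group,clinician_researcher,9pt,3,14
stakeholder_group,patient,5pt,1,20
stakeholder_group,patient,9pt,1,22
stakeholder_group,patient,5pt,2,14
stakeholder_group,patient,9pt,2,12
stakeholder_group,patient,5pt,3,10
stakeholder_group,patient,9pt,3,8
stakeholder_group,researcher,5pt,1,10
stakeholder_group,researcher,9pt,1,13
stakeholder_group,researcher,5pt,2,10
stakeholder_group,researcher,9pt,2,11
stakeholder_group,researcher,5pt,3,10
stakeholder_group,researcher,9pt,3,11
stakeholder_group,service_provider_policy_maker,5pt,1,5
stakeholder_group,service_provider_policy_maker,9pt,1,6
stakeholder_group,service_provider_policy_maker,5pt,2,3
stakeholder_group,service_provider_policy_maker,9pt,2,5
stakeholder_group,service_provider_policy_maker,5pt,3,3
stakeholder_group,service_provider_policy_maker,9pt,3,5
gender,female,5pt,1,73
gender,female,9pt,1,86
gender,female,5pt,2,57
gender,female,9pt,2,57
gender,female,5pt,3,51
gender,female,9pt,3,50
gender,male,5pt,1,27
gender,male,9pt,1,18
gender,male,5pt,2,19
gender,male,9pt,2,14
gender,male,5pt,3,18
gender,male,9pt,3,13
gender,prefer_not_to_say,5pt,1,1
gender,prefer_not_to_say,9pt,1,0
gender,prefer_not_to_say,5pt,2,0
gender,prefer_not_to_say,9pt,2,0
gender,prefer_not_to_say,5pt,3,0
gender,prefer_not_to_say,9pt,3,0
age,18-24,5pt,1,2
age,18-24,9pt,1,1
age,18-24,5pt,2,1
age,18-24,9pt,2,0
age,18-24,5pt,3,1
age,18-24,9pt,3,0
age,25-34,5pt,1,19
age,25-34,9pt,1,22
age,25-34,5pt,2,16
age,25-34,9pt,2,12
age,25-34,5pt,3,13
age,25-34,9pt,3,9
age,35-44,5pt,1,34
age,35-44,9pt,1,40
age,35-44,5pt,2,23
age,35-44,9pt,2,28
age,35-44,5pt,3,20
age,35-44,9pt,3,24
age,45-54,5pt,1,24
age,45-54,9pt,1,20
age,45-54,5pt,2,19
age,45-54,9pt,2,16
age,45-54,5pt,3,18
age,45-54,9pt,3,15
age,55-64,5pt,1,18
age,55-64,9pt,1,15
age,55-64,5pt,2,15
age,55-64,9pt,2,11
age,55-64,5pt,3,15
age,55-64,9pt,3,11
age,65+,5pt,1,4
age,65+,9pt,1,6
age,65+,5pt,2,2
age,65+,9pt,2,4
age,65+,5pt,3,2
age,65+,9pt,3,4
country,Argentina,5pt,1,1
country,Argentina,9pt,1,0
country,Argentina,5pt,2,0
country,Argentina,9pt,2,0
country,Argentina,5pt,3,0
country,Argentina,9pt,3,0
country,Australia,5pt,1,4
country,Australia,9pt,1,4
country,Australia,5pt,2,3
country,Australia,9pt,2,3
country,Australia,5pt,3,3
country,Australia,9pt,3,3
country,Austria,5pt,1,1
country,Austria,9pt,1,0
country,Austria,5pt,2,1
country,Austria,9pt,2,0
country,Austria,5pt,3,1
country,Austria,9pt,3,0
country,Belgium,5pt,1,3
country,Belgium,9pt,1,1
country,Belgium,5pt,2,3
country,Belgium,9pt,2,1
country,Belgium,5pt,3,3
country,Belgium,9pt,3,1
country,Brazil,5pt,1,1
country,Brazil,9pt,1,0
country,Brazil,5pt,2,1
country,Brazil,9pt,2,0
country,Brazil,5pt,3,1
country,Brazil,9pt,3,0
country,Canada,5pt,1,6
country,Canada,9pt,1,11
country,Canada,5pt,2,4
country,Canada,9pt,2,9
country,Canada,5pt,3,4
country,Canada,9pt,3,9
country,Colombia,5pt,1,1
country,Colombia,9pt,1,0
country,Colombia,5pt,2,1
country,Colombia,9pt,2,0
country,Colombia,5pt,3,1
country,Colombia,9pt,3,0
country,Cook Islands,5pt,1,0
country,Cook Islands,9pt,1,1
country,Cook Islands,5pt,2,0
country,Cook Islands,9pt,2,0
country,Cook Islands,5pt,3,0
country,Cook Islands,9pt,3,0
country,Croatia,5pt,1,1
country,Croatia,9pt,1,0
country,Croatia,5pt,2,0
country,Croatia,9pt,2,0
country,Croatia,5pt,3,0
country,Croatia,9pt,3,0
country,Denmark,5pt,1,1
country,Denmark,9pt,1,2
country,Denmark,5pt,2,1
country,Denmark,9pt,2,2
country,Denmark,5pt,3,1
country,Denmark,9pt,3,2
country,Egypt,5pt,1,0
country,Egypt,9pt,1,1
country,Egypt,5pt,2,0
country,Egypt,9pt,2,0
country,Egypt,5pt,3,0
country,Egypt,9pt,3,0
country,Finland,5pt,1,1
country,Finland,9pt,1,0
country,Finland,5pt,2,1
country,Finland,9pt,2,0
country,Finland,5pt,3,1
country,Finland,9pt,3,0
country,Germany,5pt,1,1
country,Germany,9pt,1,0
country,Germany,5pt,2,1
country,Germany,9pt,2,0
country,Germany,5pt,3,1
country,Germany,9pt,3,0
country,Iceland,5pt,1,1
country,Iceland,9pt,1,0
country,Iceland,5pt,2,0
country,Iceland,9pt,2,0
country,Iceland,5pt,3,0
country,Iceland,9pt,3,0
country,Iran,5pt,1,0
country,Iran,9pt,1,2
country,Iran,5pt,2,0
country,Iran,9pt,2,2
country,Iran,5pt,3,0
country,Iran,9pt,3,2
country,Ireland,5pt,1,26
country,Ireland,9pt,1,19
country,Ireland,5pt,2,18
country,Ireland,9pt,2,13
country,Ireland,5pt,3,14
country,Ireland,9pt,3,10
country,Israel,5pt,1,1
country,Israel,9pt,1,0
country,Israel,5pt,2,1
country,Israel,9pt,2,0
country,Israel,5pt,3,1
country,Israel,9pt,3,0
country,Malaysia,5pt,1,4
country,Malaysia,9pt,1,0
country,Malaysia,5pt,2,2
country,Malaysia,9pt,2,0
country,Malaysia,5pt,3,2
country,Malaysia,9pt,3,0
country,Mexico,5pt,1,0
country,Mexico,9pt,1,3
country,Mexico,5pt,2,0
country,Mexico,9pt,2,3
country,Mexico,5pt,3,0
country,Mexico,9pt,3,2
country,Nepal,5pt,1,2
country,Nepal,9pt,1,0
country,Nepal,5pt,2,2
country,Nepal,9pt,2,0
country,Nepal,5pt,3,2
country,Nepal,9pt,3,0
country,Netherlands,5pt,1,3
country,Netherlands,9pt,1,1
country,Netherlands,5pt,2,3
country,Netherlands,9pt,2,1
country,Netherlands,5pt,3,3
country,Netherlands,9pt,3,1
country,New Zealand,5pt,1,1
country,New Zealand,9pt,1,2
country,New Zealand,5pt,2,1
country,New Zealand,9pt,2,1
country,New Zealand,5pt,3,1
country,New Zealand,9pt,3,1
country,Norway,5pt,1,7
country,Norway,9pt,1,7
country,Norway,5pt,2,7
country,Norway,9pt,2,4
country,Norway,5pt,3,7
country,Norway,9pt,3,4
country,Philippines,5pt,1,0
country,Philippines,9pt,1,1
country,Philippines,5pt,2,0
country,Philippines,9pt,2,0
country,Philippines,5pt,3,0
country,Philippines,9pt,3,0
country,Poland,5pt,1,0
country,Poland,9pt,1,1
country,Poland,5pt,2,0
country,Poland,9pt,2,1
country,Poland,5pt,3,0
country,Poland,9pt,3,1
country,Portugal,5pt,1,1
country,Portugal,9pt,1,2
country,Portugal,5pt,2,1
country,Portugal,9pt,2,1
country,Portugal,5pt,3,1
country,Portugal,9pt,3,1
country,South Africa,5pt,1,0
country,South Africa,9pt,1,1
country,South Africa,5pt,2,0
country,South Africa,9pt,2,1
country,South Africa,5pt,3,0
country,South Africa,9pt,3,1
country,Sweden,5pt,1,11
country,Sweden,9pt,1,15
country,Sweden,5pt,2,9
country,Sweden,9pt,2,9
country,Sweden,5pt,3,9
country,Sweden,9pt,3,9
country,Switzerland,5pt,1,1
country,Switzerland,9pt,1,3
country,Switzerland,5pt,2,1
country,Switzerland,9pt,2,3
country,Switzerland,5pt,3,0
country,Switzerland,9pt,3,3
country,UK,5pt,1,11
country,UK,9pt,1,17
country,UK,5pt,2,8
country,UK,9pt,2,9
country,UK,5pt,3,7
country,UK,9pt,3,5
country,USA,5pt,1,11
country,USA,9pt,1,9
country,USA,5pt,2,7
country,USA,9pt,2,7
country,USA,5pt,3,6
country,USA,9pt,3,7
country,Zimbabwe,5pt,1,0
country,Zimbabwe,9pt,1,1
country,Zimbabwe,5pt,2,0
country,Zimbabwe,9pt,2,1
country,Zimbabwe,5pt,3,0
country,Zimbabwe,9pt,3,1
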