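patient_id,lesion_id,gender,age,segment,size_mm,outcome_day3,outcome_day10,outcome_final,interval_pre_mri_to_tace_days,interval_tace_to_followup_days,followup_modality
p01,l1,f,79,8,56,PR,PR,SD,1,74,CTHA
p01,l2,f,79,8,21,SD,SD,SD,1,74,CTHA
p02,l1,m,75,6,14,CR,CR,CR,8,73,CT
p02,l2,m,75,3,9,SD,CR,CR,8,73,CT
p03,l1,m,66,4,10,SD,SD,SD,1,40,CT
p03,l2,m,66,3,20,CR,CR,PR,1,40,CT
p04,l1,m,73,7,11,CR,CR,SD,1,114,CT
p04,l2,m,73,3,10,CR,CR,SD,1,114,CT
p05,l1,f,69,7,7,CR,CR,SD,1,87,CT
p05,l2,f,69,5,8,CR,CR,SD,1,87,CT
p06,l1,m,60,8,80,PR,PR,PD,3,51,MRI
p07,l1,f,56,4,15,CR,CR,CR,1,72,CT
p07,l2,f,56,1,16,CR,CR,CR,1,72,CT
p08,l1,m,68,7,44,PR,PR,PR,4,68,CT
p08,l2,m,68,3,11,CR,CR,SD,4,68,CT
p09,l1,m,71,7,11,CR,CR,PD,4,58,CT
p09,l2,m,71,3,31,CR,CR,SD,4,58,CT
p10,l1,m,42,4,18,SD,SD,SD,3,71,CT
p10,l2,m,42,3,17,SD,SD,SD,3,71,CT
p11,l1,m,56,6,36,PR,PR,PR,3,71,CTHA
p11,l2,m,56,1,29,CR,CR,CR,3,71,CTHA
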