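trial_id,study_type,variable_name,range_low,range_high,range_estimated,test_mean,test_sd,test_n,control_mean,control_sd,control_n
REF9,rct,age,75,95,true,81.30,4.80,41,81.30,4.80,41
REF10,rct,age,13,21,false,17.30,2.10,211,17.10,2.10,207
REF11,rct,age,21,50,false,36.00,8.00,37,35.00,8.00,34
REF12,rct,age_months,4,6,false,5.40,0.50,49,5.60,0.50,46
REF13,rct,age,18,80,true,29.90,7.00,344,30.20,7.00,339
REF14,rct,age,18,80,true,40.00,11.60,13,34.00,10.90,13
REF15,rct,age,19,47,false,23.68,2.72,16,25.13,5.50,15
REF16,rct,age,18,80,true,57.94,15.83,83,59.48,15.53,84
REF17,cohort,age,18,80,true,64.22,12.00,31,50.73,14.00,30
REF18,cohort,age,18,80,true,40.80,12.50,142,44.80,12.30,140
REF19,cohort,age,18,80,true,45.17,12.96,30,50.75,10.27,51
REF20,cohort,age,25,80,true,36.80,8.80,49,41.90,9.20,49
REF21,cohort,age,18,80,true,49.00,17.00,12,59.00,14.00,41
REF22,cohort,age,8,18,false,14.10,2.30,30,14.30,3.10,17
REF23,cohort,age,19,88,false,45.30,10.60,164,53.40,12.40,143
REF24,cohort,age,8,18,false,13.84,2.50,32,14.36,3.20,20
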