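trial_id,sct,a_mean,a_sd,a_n,b_mean,b_sd,b_n
REF9,1,84.58,6.20,41,84.68,6.20,41
REF9,2,84.46,5.82,41,84.44,5.93,41
REF10,1,17.02,2.42,209,17.01,2.42,209
REF10,2,17.04,2.61,209,17.03,2.60,209
REF11,1,34.44,8.16,36,34.20,7.52,35
REF11,2,35.42,8.84,36,35.17,8.40,35
REF12,1,5.04,0.82,48,5.06,0.81,47
REF12,2,4.98,0.90,48,4.98,0.89,47
REF13,1,49.36,18.07,341,49.44,18.12,342
REF13,2,47.90,18.23,341,47.98,18.30,342
REF14,1,45.64,18.29,14,40.00,15.81,12
REF14,2,54.50,18.55,14,47.17,16.92,12
REF15,1,32.12,7.68,16,31.40,8.16,15
REF15,2,30.88,7.34,16,30.33,7.72,15
REF16,1,47.94,18.78,83,48.43,19.00,84
REF16,2,48.39,18.75,83,48.86,18.94,84
REF17,1,49.39,18.64,31,48.03,17.93,30
REF17,2,51.10,17.94,31,50.03,17.74,30
REF18,1,48.49,18.11,141,48.51,18.11,141
REF18,2,49.42,17.41,141,49.45,17.52,141
REF19,1,46.15,16.88,41,45.60,16.75,40
REF19,2,49.54,19.66,41,48.98,19.34,40
REF20,1,51.49,15.98,49,51.63,16.27,49
REF20,2,55.33,16.14,49,55.43,16.36,49
REF21,1,50.44,17.21,27,48.85,16.94,26
REF21,2,50.89,19.12,27,49.65,18.33,26
REF22,1,12.78,2.62,23,13.04,2.94,24
REF22,2,12.56,3.27,23,12.75,3.46,24
REF23,1,53.09,21.34,153,53.21,21.49,154
REF23,2,52.72,19.28,153,53.00,19.53,154
REF24,1,13.00,2.95,26,12.88,2.89,26
REF24,2,12.58,2.83,26,12.46,2.72,26
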