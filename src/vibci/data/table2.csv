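subject,primary_f_low_hz,primary_f_high_hz,primary_mean_pct,primary_sd_pct,secondary_f_low_hz,secondary_f_high_hz,secondary_mean_pct,secondary_sd_pct
18,5,9,58.33,6.50,7,12,70.17,8.04
8,5,12,75.83,6.72,7,9,77.83,4.83
19,5,9,57.67,7.65,7,12,58.17,6.85
7,5,9,55.00,3.94,7,12,54.67,6.14
16,9,12,68.00,8.29,5,7,64.17,7.04
11,5,12,57.17,7.78,7,9,49.67,3.40
17,5,9,69.17,6.92,7,12,59.50,7.34
10,5,9,48.33,6.28,7,12,33.00,7.26
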