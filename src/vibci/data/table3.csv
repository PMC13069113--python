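subject,f_low_hz,f_high_hz,offline_mean_pct,offline_sd_pct,online_pct
1,5,9,61.33,6.36,50.00
2,5,9,64.00,6.42,40.00
3,5,9,69.50,8.88,51.67
4,5,7,60.33,5.95,51.67
5,5,9,68.50,4.11,61.67
6,5,9,53.67,5.72,46.67
7,5,9,55.00,3.94,45.00
8,9,12,75.83,6.72,58.33
9,9,12,68.00,7.06,48.33
10,5,9,48.33,6.28,41.67
11,9,12,57.17,7.78,50.00
12,5,9,47.17,9.37,36.67
13,9,12,54.83,6.60,40.00
14,5,7,44.17,6.36,46.67
15,5,9,78.83,8.13,66.67
16,9,12,68.00,8.29,50.00
17,5,9,69.17,6.92,68.33
18,5,9,58.33,6.50,61.67
19,5,9,57.67,7.65,45.00
20,5,9,58.67,5.95,53.33
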