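age_group,share
0-14,0.155
15-19,0.060
20-29,0.150
30-39,0.155
40-49,0.150
50-59,0.130
60-69,0.090
70-79,0.065
80+,0.045
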