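age_group,montreal,quebec,canada
0-14,0.776,0.570,0.691
15-19,0.606,0.379,0.564
20-29,0.712,0.439,0.593
30-39,0.729,0.479,0.639
40-49,0.768,0.544,0.667
50-59,0.814,0.622,0.732
60-69,0.895,0.711,0.780
70-79,0.861,0.709,0.804
80+,0.842,0.645,0.793
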