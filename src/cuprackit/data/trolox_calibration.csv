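conc_uM,replicate,absorbance
0,1,0.033
0,2,0.039
0,3,0.038
10,1,0.173
10,2,0.179
10,3,0.177
20,1,0.303
20,2,0.308
20,3,0.304
30,1,0.444
30,2,0.407
30,3,0.419
40,1,0.558
40,2,0.527
40,3,0.542
50,1,0.723
50,2,0.701
50,3,0.689
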