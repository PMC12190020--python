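frac_methanol,frac_ethanol,frac_water,replicate,absorbance
1,0,0,1,1.147
1,0,0,2,1.233
1,0,0,3,1.189
0,1,0,1,0.941
0,1,0,2,1.033
0,1,0,3,0.981
0,0,1,1,0.365
0,0,1,2,0.418
0,0,1,3,0.381
0.5,0.5,0,1,1.201
0.5,0.5,0,2,1.330
0.5,0.5,0,3,1.262
0.5,0,0.5,1,1.237
0.5,0,0.5,2,1.324
0.5,0,0.5,3,1.266
0,0.5,0.5,1,0.911
0,0.5,0.5,2,0.966
0,0.5,0.5,3,0.927
0.33,0.33,0.33,1,0.933
0.33,0.33,0.33,2,1.054
0.33,0.33,0.33,3,0.994
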