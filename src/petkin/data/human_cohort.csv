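subject_id,volume_mL,SUV55,Ki_mL_per_mL_h,R2
1,78,3.4,0.60,0.99
2,69,6.4,0.93,1.0
3,48,2.0,0.38,0.97
4,66,3.8,0.62,0.98
5,63,3.7,0.63,0.98
6,78,4.3,0.83,0.99
7,59,2.2,0.45,0.99
8,73,3.7,0.59,1.0
9,57,2.5,0.38,0.99
10,49,2.6,0.43,0.97
11,75,4.6,0.83,0.99
12,135,4.7,0.58,0.99
13,117,5.6,0.97,1.0
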