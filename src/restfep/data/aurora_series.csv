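compound,ddg_kcal,ic50_uM,ki_uM
1,1.05,289,62.5
2,0.00,75.9,16.5
3,-0.94,36.0,7.8
4,-0.73,,
5,-0.89,20.5,4.4
6,-0.49,25.6,5.5
7,0.11,26.5,5.7
8,1.12,,
9,-0.49,42,8.7
10,-0.90,11.1,2.3
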