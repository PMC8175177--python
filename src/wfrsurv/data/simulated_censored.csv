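time,removed
0.2332,7
0.3186,1
0.7247,2
0.854,4
1.0203,1
1.0555,0
1.3103,0
1.3759,0
1.4376,0
1.4585,0
1.61,0
1.7332,0
1.9045,0
2.1138,0
2.987,0
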