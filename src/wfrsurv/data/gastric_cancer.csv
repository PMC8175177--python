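time
0.047
0.115
0.121
0.132
0.164
0.197
0.203
0.260
0.282
0.296
0.334
0.395
0.458
0.466
0.501
0.507
0.529
0.534
0.540
0.570
0.641
0.644
0.696
0.841
0.863
1.099
1.219
1.271
1.326
1.447
1.485
1.553
1.581
1.589
2.178
2.343
2.416
2.444
2.825
2.830
3.578
3.658
3.743
3.978
4.003
4.033
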