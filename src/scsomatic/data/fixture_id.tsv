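category	TID1	TID2	TID3
1:Del:C:0	0.001205	0.001205	0.001807
1:Del:C:1	0.001205	0.001205	0.001807
1:Del:C:2	0.001205	0.001205	0.001807
1:Del:C:3	0.001205	0.001205	0.001807
1:Del:C:4	0.001205	0.001205	0.001807
1:Del:C:5	0.001205	0.001205	0.001807
1:Del:T:0	0.001205	0.001205	0.001807
1:Del:T:1	0.001205	0.001205	0.001807
1:Del:T:2	0.001205	0.001205	0.001807
1:Del:T:3	0.001205	0.001205	0.001807
1:Del:T:4	0.001205	0.101205	0.001807
1:Del:T:5	0.101205	0.401205	0.001807
1:Ins:C:0	0.001205	0.001205	0.001807
1:Ins:C:1	0.001205	0.001205	0.001807
1:Ins:C:2	0.001205	0.001205	0.001807
1:Ins:C:3	0.001205	0.001205	0.001807
1:Ins:C:4	0.001205	0.001205	0.001807
1:Ins:C:5	0.051205	0.001205	0.001807
1:Ins:T:0	0.001205	0.001205	0.001807
1:Ins:T:1	0.001205	0.001205	0.001807
1:Ins:T:2	0.001205	0.001205	0.001807
1:Ins:T:3	0.001205	0.001205	0.001807
1:Ins:T:4	0.201205	0.001205	0.001807
1:Ins:T:5	0.551205	0.401205	0.001807
2:Del:R:0	0.001205	0.001205	0.032607
2:Del:R:1	0.001205	0.001205	0.038311
2:Del:R:2	0.001205	0.001205	0.015006
2:Del:R:3	0.001205	0.001205	0.043981
2:Del:R:4	0.001205	0.001205	0.020423
2:Del:R:5	0.001205	0.001205	0.027195
3:Del:R:0	0.001205	0.001205	0.063311
3:Del:R:1	0.001205	0.001205	0.034287
3:Del:R:2	0.001205	0.001205	0.051912
3:Del:R:3	0.001205	0.001205	0.020777
3:Del:R:4	0.001205	0.001205	0.021578
3:Del:R:5	0.001205	0.001205	0.014169
4:Del:R:0	0.001205	0.001205	0.006324
4:Del:R:1	0.001205	0.001205	0.046148
4:Del:R:2	0.001205	0.001205	0.006699
4:Del:R:3	0.001205	0.001205	0.027751
4:Del:R:4	0.001205	0.001205	0.025019
4:Del:R:5	0.001205	0.001205	0.026961
5:Del:R:0	0.001205	0.001205	0.013621
5:Del:R:1	0.001205	0.001205	0.015507
5:Del:R:2	0.001205	0.001205	0.02044
5:Del:R:3	0.001205	0.001205	0.010336
5:Del:R:4	0.001205	0.001205	0.004896
5:Del:R:5	0.001205	0.001205	0.055827
2:Ins:R:0	0.001205	0.001205	0.001807
2:Ins:R:1	0.001205	0.001205	0.001807
2:Ins:R:2	0.001205	0.001205	0.001807
2:Ins:R:3	0.001205	0.001205	0.001807
2:Ins:R:4	0.001205	0.001205	0.001807
2:Ins:R:5	0.001205	0.001205	0.001807
3:Ins:R:0	0.001205	0.001205	0.001807
3:Ins:R:1	0.001205	0.001205	0.001807
3:Ins:R:2	0.001205	0.001205	0.001807
3:Ins:R:3	0.001205	0.001205	0.001807
3:Ins:R:4	0.001205	0.001205	0.001807
3:Ins:R:5	0.001205	0.001205	0.001807
4:Ins:R:0	0.001205	0.001205	0.001807
4:Ins:R:1	0.001205	0.001205	0.001807
4:Ins:R:2	0.001205	0.001205	0.001807
4:Ins:R:3	0.001205	0.001205	0.001807
4:Ins:R:4	0.001205	0.001205	0.001807
4:Ins:R:5	0.001205	0.001205	0.001807
5:Ins:R:0	0.001205	0.001205	0.001807
5:Ins:R:1	0.001205	0.001205	0.001807
5:Ins:R:2	0.001205	0.001205	0.001807
5:Ins:R:3	0.001205	0.001205	0.001807
5:Ins:R:4	0.001205	0.001205	0.001807
5:Ins:R:5	0.001205	0.001205	0.001807
2:Del:M:1	0.001205	0.001205	0.010865
3:Del:M:1	0.001205	0.001205	0.019042
3:Del:M:2	0.001205	0.001205	0.015284
4:Del:M:1	0.001205	0.001205	0.020889
4:Del:M:2	0.001205	0.001205	0.01401
4:Del:M:3	0.001205	0.001205	0.01397
5:Del:M:1	0.001205	0.001205	0.039146
5:Del:M:2	0.001205	0.001205	0.006348
5:Del:M:3	0.001205	0.001205	0.070234
5:Del:M:4	0.001205	0.001205	0.043786
5:Del:M:5	0.001205	0.001205	0.016593
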