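study,treatment,events,total
1,A,36,46
1,B,36,49
2,A,183,367
2,B,171,364
3,A,106,348
3,B,83,347
4,A,74,107
4,E,64,107
5,B,15,46
5,C,19,49
6,C,17,109
6,D,15,108
7,C,89,470
7,D,77,466
8,C,40,111
8,E,39,114
9,C,17,150
9,F,15,151
10,C,3,31
10,H,3,33
11,C,13,114
11,H,12,117
12,E,10,197
12,F,8,195
13,E,45,421
13,F,49,422
14,E,13,153
14,F,13,153
15,E,49,331
15,F,43,333
16,F,1,44
16,G,1,47
17,F,3,85
17,G,2,83
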