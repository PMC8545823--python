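item_id,ST,CS,SE,OC
1,1,9,17,25
2,2,10,18,26
3,3,11,19,27
4,4,12,20,28
5,1,10,19,28
6,2,11,20,25
7,3,12,17,26
8,4,9,18,27
9,5,13,21,29
10,6,14,22,30
11,7,15,23,31
12,8,16,24,32
13,5,14,23,32
14,6,15,24,29
15,7,16,21,30
16,8,13,22,31
17,6,13,20,27
18,3,14,21,28
19,4,11,22,29
20,5,12,19,30
21,2,9,24,31
22,7,10,17,32
23,8,15,18,25
24,1,16,23,26
25,1,11,21,31
26,3,13,23,25
27,5,15,17,27
28,7,9,19,29
29,2,12,22,32
30,4,14,24,26
31,6,16,18,28
32,8,10,20,30
33,1,12,23,26
34,2,13,24,27
35,3,14,17,28
36,4,15,18,29
37,5,16,19,30
38,6,9,20,31
39,7,10,21,32
40,8,11,22,25
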