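subject_id,gender,age,course_months,n_seizures,impaired_flag
1,F,6,0.4,1,0
2,M,7,1.5,2,1
3,M,10,1,2,0
4,F,6,0.9,1,1
5,M,9,3.8,2,1
6,M,9,0.3,1,0
7,F,11,0.6,2,0
8,F,6,1.2,3,1
9,M,10,0.9,1,0
10,M,6,2.1,2,1
11,F,6,0.9,2,0
12,M,7,2.9,3,1
13,F,7,2.5,2,1
14,M,6,0.7,2,0
15,F,8,0.8,2,0
16,M,6,1.4,2,1
17,F,6,0.1,1,0
18,M,7,0.1,1,0
19,M,6,0.2,1,0
20,F,6,3.6,3,1
21,M,7,5.5,3,1
22,F,7,2,3,1
23,F,10,0.3,1,0
24,F,6,2.1,4,1
25,F,7,0.3,1,0
26,M,7,2.2,3,1
27,M,8,0.8,2,0
28,F,8,3.5,5,1
29,M,7,1,1,0
30,F,9,2.7,4,1
31,M,8,0.6,3,0
32,F,11,0.6,2,0
33,M,6,3.1,3,1
34,F,7,3.2,4,1
35,M,10,0.9,2,0
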