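no,category
1,aldehyde
2,aldehyde
3,ketone
4,aldehyde
5,aldehyde
6,aldehyde
7,hydrocarbon
8,ketone
9,alcohol
10,ketone
11,hydrocarbon
12,aldehyde
13,aldehyde
14,aldehyde
15,hydrocarbon
16,hydrocarbon
17,ketone
18,hydrocarbon
19,aldehyde
20,alcohol
21,hydrocarbon
22,aldehyde
23,aldehyde
24,alcohol
25,aldehyde
26,ketone
27,ketone
28,alcohol
29,alcohol
30,alcohol
31,hydrocarbon
32,alcohol
33,ketone
34,ketone
35,alcohol
36,alcohol
37,aldehyde
38,ketone
39,ester
40,hydrocarbon
41,ketone
42,ketone
43,methoxy-phenolic
44,phenolic
45,ketone
46,aldehyde
47,aldehyde
48,ester
49,phenolic
50,alcohol
51,alcohol
52,alcohol
53,ketone
54,alcohol
55,ester
56,alcohol
57,aldehyde
58,aldehyde
59,aldehyde
60,aldehyde
61,alcohol
62,methoxy-phenolic
63,ketone
64,alcohol
65,aldehyde
66,aldehyde
67,phenolic
68,hydrocarbon
69,ketone
70,aldehyde
71,ester
72,methoxy-phenolic
73,hydrocarbon
74,methoxy-phenolic
75,ketone
76,hydrocarbon
77,lactone
78,aldehyde
79,ketone
80,ketone
81,ketone
82,aldehyde
83,ketone
84,ketone
85,ketone
86,ketone
87,ketone
88,hydrocarbon
89,ketone
90,hydrocarbon
91,ketone
92,ketone
93,ketone
94,hydrocarbon
95,hydrocarbon
96,phenolic
97,hydrocarbon
98,lactone
99,alcohol
100,alcohol
101,ester
102,hydrocarbon
103,alcohol
104,aldehyde
105,alcohol
106,alcohol
107,ester
108,ketone
109,ester
110,ester
111,aldehyde
112,alcohol
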