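id,reliability,reliability_class,expert_class
01,0.47,Mean,Mean
02,0.69,High,High
03,0.68,High,High
04,0.63,High,Mean
05,0.68,High,Mean
06,0.81,High,High
07,0.67,High,Mean
08,0.82,High,High
09,0.89,High,High
10,0.57,Mean,Mean
11,0.41,Low,Low
12,0.76,High,High
13,0.57,Mean,High
14,0.43,Low,Low
15,0.66,High,Mean
16,0.42,Low,Low
17,0.53,Mean,Mean
18,0.47,Mean,Mean
19,0.57,Mean,Mean
20,0.46,Mean,Mean
21,0.43,Low,Low
22,0.58,Mean,Mean
23,0.61,Mean,High
24,0.50,Mean,Mean
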