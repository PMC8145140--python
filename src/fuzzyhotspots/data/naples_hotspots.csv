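id,area_km2,std_dev,reliability
01,0.06,0.045,0.47
02,0.24,0.028,0.69
03,0.31,0.031,0.68
04,0.34,0.033,0.63
05,0.81,0.033,0.68
06,0.89,0.025,0.81
07,0.92,0.032,0.67
08,0.97,0.024,0.82
09,1.00,0.022,0.89
10,1.08,0.033,0.57
11,1.18,0.050,0.41
12,1.47,0.026,0.76
13,1.59,0.034,0.57
14,1.66,0.044,0.42
15,1.76,0.033,0.66
16,1.79,0.042,0.43
17,2.10,0.035,0.53
18,2.14,0.039,0.47
19,3.51,0.030,0.57
20,3.52,0.048,0.46
21,5.03,0.045,0.43
22,5.07,0.037,0.58
23,5.30,0.035,0.61
24,8.91,0.043,0.50
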