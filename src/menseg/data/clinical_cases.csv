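case,gt,sys,tp,fp,fn,tn,pm,cr
1,2132,3512,2012,1500,120,61904,94.37,0.59
2,855,4440,0,4440,855,60241,0.00,-2.60
3,4271,4313,4118,195,153,61070,96.42,0.94
4,1183,990,865,125,318,64228,73.12,0.68
5,4517,3577,3434,143,1083,60876,76.02,0.74
6,2270,2452,2180,272,90,62994,96.04,0.90
7,1100,1370,1099,271,1,64165,99.91,0.88
8,761,648,623,25,138,64750,81.87,0.80
9,5607,4559,4544,15,1063,59914,81.04,0.81
10,1081,1126,935,191,146,64264,86.49,0.78
11,2013,3104,0,3104,2013,60419,0.00,-0.77
12,2500,2298,2246,52,254,62984,89.84,0.89
13,1968,3198,1957,1241,11,62327,99.44,0.68
14,442,374,359,15,83,65079,81.22,0.80
15,942,2764,0,2764,942,61830,0.00,-1.47
16,5549,6967,5482,1485,67,58502,98.79,0.85
17,2137,2657,261,2396,1876,61003,12.21,-0.44
18,732,1508,0,1508,732,63296,0.00,-1.03
19,4379,4205,4158,47,221,61110,94.95,0.94
20,2589,2650,2455,195,134,62752,94.82,0.91
21,1397,1554,1306,248,91,63891,93.49,0.85
22,4702,6114,4584,1530,118,59304,97.49,0.81
23,1560,1537,1408,129,152,63847,90.26,0.86
24,1384,1650,1183,467,201,63685,85.48,0.69
25,588,719,566,153,22,64795,96.26,0.83
26,1662,2012,1586,426,76,245750,95.43,0.83
27,1715,2012,1417,595,298,245530,82.62,0.65
28,4495,4825,4359,466,136,242870,96.97,0.92
29,1329,206,206,0,1123,246510,15.50,0.16
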