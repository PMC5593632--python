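compound_id,exp,pred,R1,R2,split
1,8.97,9.41,1.47,2.17,train
2,8.59,8.56,1.47,1.32,train
3,8.67,8.46,0.53,2.17,train
4,9.06,8.93,0.53,2.63,train
5,8.39,8.35,0.53,2.05,train
6,9.49,9.48,-2.09,5.81,train
7,9.52,9.46,-2.09,5.79,train
8,5.50,5.01,-2.09,1.34,train
9,3.25,3.51,-2.09,-0.17,train
10,2.98,3.01,-2.09,-0.67,train
11,3.23,3.79,-2.09,0.12,train
12,3.36,3.86,-2.09,0.19,train
13,3.44,3.33,-2.09,-0.34,train
14,5.11,4.98,-0.83,0.06,train
15,3.04,2.89,-2.09,-0.79,train
16,3.20,3.35,-2.09,-0.32,train
17,3.41,3.30,-2.09,-0.37,train
18,3.82,3.69,-2.09,0.02,train
19,4.99,5.03,-2.09,1.36,train
20,5.54,5.44,-2.09,1.76,train
21,5.11,4.74,-2.09,1.05,train
22,5.20,4.91,-2.09,1.24,train
23,5.57,5.60,-2.09,1.92,train
24,7.39,7.31,1.05,0.49,train
25,8.29,8.35,0.92,1.66,train
26,8.28,8.25,0.92,1.56,train
27,8.25,8.17,0.92,1.49,train
28,7.77,7.92,0.92,1.23,train
29,7.05,7.09,0.92,0.40,train
30,7.29,7.18,0.92,0.49,train
31,7.58,7.78,0.10,1.91,train
32,7.68,7.85,0.10,1.99,train
33,7.91,7.97,-2.09,4.29,train
34,7.93,7.74,-2.09,4.06,train
35,8.17,8.13,-2.09,4.46,train
36,9.49,9.48,-2.09,5.81,train
37,8.85,9.13,-2.09,5.45,train
38,7.89,7.78,1.47,0.54,train
39,6.89,6.77,0.46,0.54,train
40,6.41,6.54,0.22,0.54,train
41,5.32,5.27,-0.09,-0.41,train
42,6.77,6.83,1.47,-0.41,train
43,7.67,7.82,1.47,0.58,train
44,9.60,9.14,1.47,1.90,train
45,7.49,7.74,0.53,1.45,train
46,7.52,7.57,0.53,1.27,train
47,8.16,8.19,0.53,1.90,train
48,9.57,9.87,1.47,2.63,test
49,9.17,9.29,1.47,2.05,test
50,5.66,4.96,-2.09,1.29,test
51,5.47,5.52,-2.09,1.84,test
52,5.63,5.15,-0.67,0.06,test
53,7.23,8.05,1.05,1.23,test
54,7.53,7.06,0.10,1.19,test
55,7.56,7.28,0.10,1.41,test
56,7.35,7.76,1.45,0.54,test
57,6.34,6.71,0.40,0.54,test
58,6.54,6.22,-0.09,0.54,test
59,5.43,5.59,0.22,-0.41,test
60,7.42,8.23,0.53,1.93,test
61,7.45,8.32,0.53,2.02,test
FB,,5.95,1.21,0.17,query
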