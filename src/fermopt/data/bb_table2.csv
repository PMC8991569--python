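run,CaCl2,TraceElement,Volume,response
1,0,0,0,0.58
2,-1,1,0,0.59
3,0,-1,-1,0.44
4,1,0,-1,0.51
5,0,1,-1,0.41
6,1,-1,0,1.01
7,-1,-1,0,0.44
8,0,1,1,0.89
9,1,0,1,0.90
10,0,0,0,0.69
11,0,-1,1,0.77
12,-1,0,-1,0.28
13,-1,0,1,1.00
14,1,1,0,0.98
15,0,0,0,0.65
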