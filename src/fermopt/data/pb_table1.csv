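run,Glucose,KNO3,K2HPO4,CaCl2,MgSO4,Tyrosine,TraceElement,pH,CultureAge,InoculumSize,Volume,response
1,-1,-1,-1,1,1,1,-1,1,1,-1,1,0.538
2,-1,-1,1,1,1,-1,1,1,-1,1,-1,0.217
3,-1,1,-1,-1,-1,1,1,1,-1,1,1,0.327
4,1,1,-1,1,-1,-1,-1,1,1,1,-1,0.531
5,-1,1,1,-1,1,-1,-1,-1,1,1,1,0.340
6,1,-1,1,1,-1,1,-1,-1,-1,1,1,0.876
7,1,-1,1,-1,-1,-1,1,1,1,-1,1,0.219
8,1,-1,-1,-1,1,1,1,-1,1,1,-1,0.029
9,1,1,1,-1,1,1,-1,1,-1,-1,-1,0.046
10,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1,0.091
11,-1,1,1,1,-1,1,1,-1,1,-1,-1,0.153
12,1,1,-1,1,1,-1,1,-1,-1,-1,1,0.598
13,0,0,0,0,0,0,0,0,0,0,0,0.431
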