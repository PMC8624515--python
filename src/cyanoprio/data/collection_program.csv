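start_min,end_min,fraction
1.00,2.30,A
2.30,3.60,B
3.60,4.90,C
4.90,6.20,D
6.20,7.50,E
7.50,8.80,F
8.80,10.36,G
10.36,11.50,H
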