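valence,s_sec,mean_sec,sd_sec
P,2,2.335,0.690
P,4,3.717,0.869
P,6,4.799,1.102
N,2,2.136,0.571
N,4,3.456,0.876
N,6,4.839,1.106
E,2,2.210,0.676
E,4,3.496,0.937
E,6,4.527,1.212
All,2,2.227,0.646
All,4,3.556,0.892
All,6,4.722,1.137
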