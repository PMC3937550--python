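iads_id,group,subgroup,pleasantness_mean,arousal_mean
200,P,a,6.58,6.27
254,P,a,6.58,6.27
802,P,a,6.58,6.27
817,P,a,6.58,6.27
820,P,a,6.58,6.27
110,P,b,7.22,5.78
351,P,b,7.22,5.78
366,P,b,7.22,5.78
717,P,b,7.22,5.78
810,P,b,7.22,5.78
220,P,c,7.14,6.60
311,P,c,7.14,6.60
201,P,c,7.14,6.60
355,P,c,7.14,6.60
816,P,c,7.14,6.60
252,N,a,3.33,5.96
293,N,a,3.33,5.96
600,N,a,3.33,5.96
611,N,a,3.33,5.96
709,N,a,3.33,5.96
255,N,b,2.82,6.35
288,N,b,2.82,6.35
296,N,b,2.82,6.35
712,N,b,2.82,6.35
730,N,b,2.82,6.35
250,N,c,3.29,6.51
260,N,c,3.29,6.51
282,N,c,3.29,6.51
711,N,c,3.29,6.51
732,N,c,3.29,6.51
113,E,a,4.97,4.41
246,E,a,4.97,4.41
705,E,a,4.97,4.41
720,E,a,4.97,4.41
724,E,a,4.97,4.41
102,E,b,4.87,4.55
130,E,b,4.87,4.55
376,E,b,4.87,4.55
700,E,b,4.87,4.55
701,E,b,4.87,4.55
322,E,c,4.80,4.67
361,E,c,4.80,4.67
627,E,c,4.80,4.67
722,E,c,4.80,4.67
728,E,c,4.80,4.67
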