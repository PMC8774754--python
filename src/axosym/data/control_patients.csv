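id,group,cci_pct,genetic_defect,hsva,tem_defect,aa_pct
78,control,30,not tested,N,No,2
66,control,40,not tested,N,No,8
2,control,20,not tested,N,No,10
69,control,50,not tested,N,No,12
73,control,30,not tested,N,No,12
43,control,20,not tested,N,No,14
68,control,50,Not identified,N,No,14
70,control,40,not tested,N,No,14
99,control,30,not tested,N,No,14
28,control,30,not tested,N,No,18
36,control,20,not tested,N,No,18
67,control,40,not tested,N,No,18
85,control,40,not tested,N,No,18
86,control,40,not tested,N,No,18
58,control,40,VUS RSPH4,N,No,22
34,control,20,not tested,N,No,24
40,control,40,not tested,N,No,34
98,control,30,not tested,N,No,36
25,control,40,not tested,N,No,44
59,control,60,VUS CCDC103,N,No,63
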