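id,group,cci_pct,genetic_defect,hsva,tem_defect,aa_pct
23,PCD,40,Not identified,Dyskinetic,No,38
62,PCD,60,DNAH9,Dyskinetic,C1,38
74,PCD,90,DNAH5,Dyskinetic,C1,40
83,PCD,50,DNAH5,Immotile,C1,40
27,PCD,40,DNAH5,Immotile,C1,42
44,PCD,60,TTC25,Immotile,C1,42
47,PCD,70,DNAH5,Immotile,C1,44
55,PCD,50,DNAH9,Immotile,No,44
4,PCD,40,DNAAF1,Immotile,C1,46
51,PCD,60,Not identified,Dyskinetic,No,46
14,PCD,60,RSPH1,Dyskinetic,C2,48
32,PCD,70,DYX1C1,Immotile,C1,48
80,PCD,60,Not identified,Dyskinetic,No,48
91,PCD,60,RSPH1,Dyskinetic,No,48
6,PCD,50,RSPH1,Normal,C2,50
81,PCD,70,DNAH11,Immotile,No,50
22,PCD,40,DNAH5,Immotile,C1,56
16,PCD,30,Not identified,Immotile,C1,58
92,PCD,60,RSPH1,Dyskinetic,No,66
21,PCD,60,DNAH5,Immotile,C1,68
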