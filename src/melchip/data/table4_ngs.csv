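patient,is_cell_line,biochip,ngs,sanger,clamp_sanger
2,0,BRAF:c.1799T>A,BRAF:c.1799T>A,,
31,0,WT,WT,,
52,0,BRAF:c.1799T>A,BRAF:c.1799T>A,,
91,0,WT,WT,,
92,0,BRAF:c.1799T>A,BRAF:c.1799T>A,,
93,0,NRAS:c.181C>A,WT,WT,NRAS:c.181C>A
94,0,BRAF:c.1799T>A;MAP2K1:c.370C>T,BRAF:c.1799T>A;MAP2K1:c.370C>T,,
95,0,BRAF:c.1799T>A,BRAF:c.1799T>A,,
96,0,BRAF:c.1799T>A,WT,,
97,0,BRAF:c.1799T>A,BRAF:c.1799T>A,,
98,0,WT,WT,,
99,0,BRAF:c.1798_1799delGTinsAA,BRAF:c.1798_1799delGTinsAA,,
100,0,BRAF:c.1799T>A,BRAF:c.1799T>A,,
101,0,WT,KIT:c.1621A>C,,
102,0,BRAF:c.1799T>A,BRAF:c.1799T>A,,
103,0,NRAS:c.182A>C,NRAS:c.182A>C,,
104,0,WT,WT,,
105,0,BRAF:c.1799T>A,BRAF:c.1799T>A,,
106,0,BRAF:c.1798_1799delGTinsAA,KIT:c.148G>T,WT,BRAF:c.1798_1799delGTinsAA
107,0,BRAF:c.1799T>A,BRAF:c.1799T>A,,
108,0,NRAS:c.37G>C,NRAS:c.37G>C,,
109,0,NRAS:c.181C>A,NRAS:c.181C>A,,
110,0,BRAF:c.1799T>A,BRAF:c.1799T>A,,
111,0,BRAF:c.1799T>A,KIT:c.1621A>C;BRAF:c.1799T>A,,
112,0,NRAS:c.181C>A,WT,WT,NRAS:c.181C>A
SK-MEL2,1,NRAS:c.182A>G,NRAS:c.182A>G;KIT:c.1621A>C;KIT:c.733G>A,,
Mel Il,1,BRAF:c.1798_1799delGTinsAA,BRAF:c.1798_1799delGTinsAA;BRAF:c.1165C>T,,
Mel Ibr,1,BRAF:c.1799T>A,BRAF:c.1799T>A,,
Mel Rac,1,NRAS:c.182A>G,NRAS:c.182A>G,,
Mel Cher,1,NRAS:c.182A>G,WT,WT,NRAS:c.182A>G
Mel Z,1,BRAF:c.1799T>A,BRAF:c.1799T>A,,
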