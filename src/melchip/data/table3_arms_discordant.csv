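patient,biochip,arms,sanger,clamp_sanger
163,BRAF:c.1799T>A,WT,BRAF:c.1799T>A,BRAF:c.1799T>A
191,BRAF:c.1798_1799delGTinsAA,WT,BRAF:c.1798_1799delGTinsAA,BRAF:c.1798_1799delGTinsAA
219,WT,BRAF:c.1798_1799delGTinsAG,WT,BRAF:c.1800G>A
223,WT,BRAF:c.1799T>A,WT,WT
226,WT,BRAF:c.1798_1799delGTinsAA,WT,WT
235,BRAF:c.1798G>A,WT,WT,BRAF:c.1798G>A
238,WT,BRAF:c.1799T>A,BRAF:c.1797_1798insACA,BRAF:c.1797_1798insACA
239,BRAF:c.1799T>A,BRAF:c.1798_1799delGTinsAA,WT,BRAF:c.1799T>A
241,WT,BRAF:c.1798_1799delGTinsAA,WT,WT
242,WT,BRAF:c.1798_1799delGTinsAA,WT,WT
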