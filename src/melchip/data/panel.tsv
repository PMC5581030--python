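gene	protein_change	cdna_change	group_id
BRAF	V600E	c.1799T>A	BRAF-600
BRAF	V600E	c.1799_1800delTGinsAA	BRAF-600
BRAF	V600K	c.1798_1799delGTinsAA	BRAF-600
BRAF	V600R	c.1798_1799delGTinsAG	BRAF-600
BRAF	V600M	c.1798G>A	BRAF-600
BRAF	V600G	c.1799T>G	BRAF-600
BRAF	V600D	c.1799_1800delTGinsAT	BRAF-600
NRAS	G12C	c.34G>T	NRAS-12/13
NRAS	G12S	c.34G>A	NRAS-12/13
NRAS	G12D	c.35G>A	NRAS-12/13
NRAS	G13R	c.37G>C	NRAS-12/13
NRAS	G13D	c.38G>A	NRAS-12/13
NRAS	G13V	c.38G>T	NRAS-12/13
NRAS	Q61P	c.182A>C	NRAS-61
NRAS	Q61R	c.182A>G	NRAS-61
NRAS	Q61H	c.183A>C	NRAS-61
NRAS	Q61H	c.183A>T	NRAS-61
NRAS	Q61K	c.181C>A	NRAS-61
NRAS	Q61L	c.182A>T	NRAS-61
KIT	W557R	c.1669T>A	KIT-557/559
KIT	W557R	c.1669T>C	KIT-557/559
KIT	V559A	c.1676T>C	KIT-557/559
KIT	V559D	c.1676T>A	KIT-557/559
KIT	L576P	c.1727T>C	KIT-576
KIT	K642E	c.1924A>G	KIT-642
KIT	D816H	c.2446G>C	KIT-816
KIT	D816Y	c.2446G>T	KIT-816
KIT	D816V	c.2447A>T	KIT-816
GNAQ	Q209P	c.626A>C	GNAQ-209
GNAQ	Q209L	c.626A>T	GNAQ-209
GNAQ	Q209R	c.626A>G	GNAQ-209
GNA11	Q209L	c.626A>T	GNA11-209
GNA11	Q209P	c.626A>C	GNA11-209
MAP2K1	C121S	c.361T>A	MAP2K1-121/124
MAP2K1	C121S	c.362G>C	MAP2K1-121/124
MAP2K1	P124S	c.370C>T	MAP2K1-121/124
MAP2K1	P124L	c.371C>T	MAP2K1-121/124
MAP2K2	F57C	c.170T>G	MAP2K2-57/60
MAP2K2	Q60P	c.179A>C	MAP2K2-57/60
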