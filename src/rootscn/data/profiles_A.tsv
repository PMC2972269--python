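# Cell-type expression profiles, model family A
cell_type	PLT	Auxin	ARF	Aux/IAA	SHR	SCR	JKD	MGP	WOX5
QC	1	1	1	0	1	1	1	0	1
vascular	1	1	1	0	1	0	0	0	0
CEI	1	1	1	0	1	1	1	1	0
CEpI	1	1	1	0	0	0	0	0	0
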