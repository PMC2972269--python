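# Cell-type expression profiles, model family B
# free: vascular:CLEX
cell_type	PLT	Auxin	ARF	Aux/IAA	SHR	SCR	JKD	MGP	WOX5	CLEX
QC	1	1	1	0	1	1	1	0	1	0
vascular	1	1	1	0	1	0	0	0	0	1
CEI	1	1	1	0	1	1	1	1	0	1
CEpI	1	1	1	0	0	0	0	0	0	0
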