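gene	diplotype	phenotype	actionable
CYP2D6	*1/*1	NM	false
CYP2D6	*1/*4	IM	true
CYP2D6	*4/*4	PM	true
CYP3A5	*1/*1	NM	true
CYP3A5	*1/*3	IM	true
CYP3A5	*3/*3	PM	false
VKORC1	*1/*1	1173CC, normal activity	false
VKORC1	*1/1173T	1173CT, moderately decreased activity	true
VKORC1	1173T/1173T	1173TT, decreased activity	true
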