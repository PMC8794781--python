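gene	allele	variants
CYP2D6	*1
CYP2D6	*4	chr22:42128945:C>T;chr22:42130692:G>A
CYP3A5	*1
CYP3A5	*3	chr7:99672916:C>T
VKORC1	*1
VKORC1	1173T	chr16:31093557:G>A
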