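gene	drug	source
CYP2D6	codeine	DPWG
CYP2D6	codeine	CPIC
CYP2D6	tamoxifen	DPWG
CYP2D6	tamoxifen	CPIC
CYP3A5	tacrolimus	DPWG
CYP3A5	tacrolimus	CPIC
VKORC1	acenocoumarol	DPWG
VKORC1	phenprocoumon	DPWG
VKORC1	warfarin	CPIC
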