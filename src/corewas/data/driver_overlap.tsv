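gene	driver_list	category
BRCA2	primary_bc	TSG
FOXP1	primary_bc	TSG
ZFP36L1	primary_bc	TSG
TBX3	primary_bc	TSG
MAP3K1	primary_bc	TSG
CHEK2	primary_bc	TSG
CASP8	fabric	ONC
CDKN2A	fabric	TSG
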