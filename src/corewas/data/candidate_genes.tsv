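gene	evidence	excluded	fg_coding_variants	fg_coding_phenotypes	fg_cs_subtype	shared_driver	clinical_panel	literature	functional_class
ADAM29	a	0	0	0	ER+			No	Proteolysis/Cell adhesion
ALS2CR12	e	0	1	1	ER-			No	Cell projection
APOBEC3A	e	0	0	0	ER+			No	DNA/RNA editing
ARHGEF5	b	1	0	0				No	Rho GTPase signaling
ATM	a	0	1	2	ER+		I,M	Yes	DNA damage repair
BRCA2	c,f	0	2	2	ER+	TSG	I,M	Yes	DNA repair (homologous recombination)
CASP8	c	0	1	2		ONC		Yes	Apoptosis regulation
CCDC170	g,i	0	2	6				Yes	Structural protein (CC domain)
CCDC88C	b	1	0	0				No	Cell migration signaling
CCDC91	f	0	0	0				No	Vesicle trafficking
CDKN2A	c	0	0	0		TSG		Yes	Cell cycle control
CDKN2B	b	1	0	0				No	Cell cycle control
CHEK2	c,d,g	0	3	3	Shared	TSG	I,M	Yes	DNA damage checkpoint
DIRC3	e	0	0	0	ER+			Yes	Non-coding RNA regulator
DNAJC1	a	0	0	0	ER+			No	Protein folding (HSP40 chaperone)
EBF1	a	0	0	0				No	Transcription regulation
ESR1	a,i	0	0	0	ER+			Yes	Nuclear hormone receptor
EXO1	a	0	1	2	ER+			Yes#	DNA repair/recombination
FGFR2	a,i	0	0	0	Shared			Yes	Receptor tyrosine kinase/Signaling
FOXP1	c	0	0	0		TSG		No	Transcription regulation
FTO	a	0	0	0	Shared			No	RNA demethylase/Epigenetics
HNF4G	b	1	0	0				No	Transcription regulation
LMX1B	a	0	0	0				No	Transcription regulation
LSP1	a,g	0	3	3	ER+			Yes	Actin cytoskeleton regulation
MAP3K1	b,c,i	0	1	2		TSG		Yes	MAPK signaling pathway
MLLT10	h	0	0	0				No	Chromatin remodeling/Transcription
MRPS30	b,g,i	0	1	4				No	Mitochondrial translation
NEK10	b,g,i	0	2	2				Yes	Cell cycle kinase
PAX9	a,i	0	0	0	ER+			No	Transcription regulation
PALB2	a	0	1	3	Shared		I,M	Yes	DNA repair (homologous recombination)
PEX14	d	0	0	0				No	Peroxisomal membrane transport
POU5F1B	a	0	1	2	ER+			No	Transcription regulation
RANBP9	d	0	0	0	ER+			No	Protein scaffolding
SETBP1	a	0	0	0				No	Transcription regulation
SLC4A7	e,i	0	0	0	ER+			Yes	Ion transport
SMC2	b	1	0	0				No	Chromosome condensation
STXBP4	d	0	2	2				No	Vesicular transport
TBX3	c	0	0	0		TSG		Yes	Transcription regulation
TCF7L2	b	1	0	0				No	Transcription regulation
TLR1	b	1	0	0				No	Innate immune receptor
TNS1	a	0	0	0				No	Focal adhesion signaling
TOX3	b,i	0	0	0	ER-			Yes	Transcription regulation
ZFP36L1	c,f	0	0	0		TSG		No	mRNA decay/Post-transcription
ZMIZ1	a	0	0	0	ER+			Yes	Transcription coactivation
ZNF365	a	0	1	2	Shared			Yes	Transcription/DNA repair
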