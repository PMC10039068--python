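AML_RELEVANT_DEFAULT	curated default list of genes recurrently implicated in AML biology; a convenience starting point, not a canonical signature — supply your own GMT for real analyses	FLT3	NPM1	DNMT3A	IDH1	IDH2	TET2	RUNX1	TP53	NRAS	KRAS	CEBPA	WT1	KIT	ASXL1	SRSF2	SF3B1	U2AF1	STAG2	BCOR	PHF6	EZH2	GATA2	PTPN11	JAK2	KMT2A	MECOM	DEK	NUP214	PML	RARA	CBFB	MYH11	BCL2	MCL1
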