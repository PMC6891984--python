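# term_id	entity_type	canonical_name	synonyms (pipe-separated)
3717	gene	JAK2	JAK2
1956	gene	EGFR	EGFR|ERBB1|HER1
672	gene	BRCA1	BRCA1
675	gene	BRCA2	BRCA2
2064	gene	ERBB2	ERBB2|HER2|HER-2|Her2|neu
5925	gene	RB1	RB1|retinoblastoma
673	gene	BRAF	BRAF
25	gene	ABL1	ABL1|ABL
613	gene	BCR	BCR
4609	gene	MYC	MYC
2475	gene	MTOR	MTOR|mTOR
3845	gene	KRAS	KRAS
7157	gene	TP53	TP53|p53
1029	gene	CDKN2A	CDKN2A|p16
5728	gene	PTEN	PTEN
834	gene	CASP1	CASP1|ICE|caspase 1
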