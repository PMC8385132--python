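KEGG_VALINE_LEUCINE_AND_ISOLEUCINE_DEGRADATION	KEGG pathway hsa00280 (branched-chain amino acid degradation), MSigDB C2 curated membership	ABAT	ACAA1	ACAA2	ACAD8	ACADM	ACADS	ACADSB	ACAT1	ACAT2	ALDH1B1	ALDH2	ALDH3A2	ALDH6A1	ALDH7A1	ALDH9A1	AOX1	AUH	BCAT1	BCAT2	BCKDHA	BCKDHB	BCKDK	DBT	DLD	ECHS1	EHHADH	HADH	HADHA	HADHB	HIBADH	HIBCH	HMGCL	HMGCS1	HMGCS2	HSD17B10	IVD	MCCC1	MCCC2	MCEE	MUT	OXCT1	OXCT2	PCCA	PCCB
BIOTIN_DEPENDENT_CARBOXYLASES	Manually defined: subunit genes of the five human biotin-dependent carboxylases (ACC1, ACC2, PC, PCC, MCC)	ACACA	ACACB	PC	PCCA	PCCB	MCCC1	MCCC2
KEGG_PROPANOATE_METABOLISM	KEGG pathway hsa00640 (propanoate metabolism), MSigDB C2 curated membership	ABAT	ACACA	ACACB	ACADM	ACAT1	ACAT2	ACSS1	ACSS2	ACSS3	ALDH1B1	ALDH2	ALDH3A2	ALDH6A1	ALDH7A1	ALDH9A1	ECHS1	EHHADH	HADHA	HIBCH	LDHA	LDHB	MCEE	MLYCD	MUT	PCCA	PCCB	SUCLA2	SUCLG1	SUCLG2
KEGG_BUTANOATE_METABOLISM	KEGG pathway hsa00650 (butanoate metabolism), MSigDB C2 curated membership	AACS	ABAT	ACADS	ACAT1	ACAT2	ACSM3	ALDH1B1	ALDH2	ALDH3A2	ALDH5A1	ALDH7A1	ALDH9A1	BDH1	BDH2	ECHS1	EHHADH	GAD1	GAD2	HADH	HMGCL	HMGCS1	HMGCS2	L2HGDH	OXCT1	OXCT2	PDHA1	PDHA2	PDHB
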