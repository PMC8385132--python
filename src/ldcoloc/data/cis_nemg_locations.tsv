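chrom	t2d_gwas_e	t2d_gwas_a	t2d_metabo_e	cis_nemg	eqtl_pos	tier
1	26006625		26003695	MTFR1L	25900571	bonferroni
1	26006625		26003695	CLIC4	26002616	bonferroni
1	26006625		26003695	CLIC4	25900772	bonferroni
1	234270220	234273988	NA	COA6	234338743	bonferroni
1	234270220	234273988	NA	TOMM20	234309446	bonferroni
2		204023399	203970861	NIF3L1	203798637	bonferroni
2		204023399	203970861	FLJ38973	204126463	bonferroni
2		204023399	203970861	MARS2	203820504	bonferroni
2		204023399	203970861	CPS1	204126514	bonferroni
2	227080369		227021099	MFF	227151692	bonferroni
3	67744088	67685265	NA	SLC25A26	67577196	bonferroni
3	123048537		123061689	CCDC58	122876198	bonferroni
3	120573472	120555505	NA	NDUFB4	120573615	bonferroni
3	132436519		132429438	ACAD11	132451038	bonferroni
3	183260285	183210822	NA	MCCC1	183260250	bonferroni
4	91942692	91950656	NA	PDHA2	91947875	bonferroni
4	104004185		103936988	CISD2	104141231	bonferroni
6	112808197	112750188	NA	GPAM	112800751	bonferroni
6	127539286		127502744	TRMT11	127479024	bonferroni
6	127539286		127502744	HINT3	127357421	bonferroni
10	94499812		94479016	Mar-05	94488072	bonferroni
10	104786704		104841790	SFXN2	104732175	bonferroni
11	8551677		8637191	CYB5R2	8667032	bonferroni
11	43879353		43879882	ALKBH3	43607412	bonferroni
11	65575917		65600493	MRPL11	65466334	bonferroni
12	56618300		55152275	GLS2	56628724	bonferroni
12	56618300		55152275	SUOX	56621500	bonferroni
12	112991642		112988341	ALDH2	112229375	bonferroni
12	106406604	106384733	NA	MTERF2	106410234	bonferroni
12	121317223		121243696	ACADS	121372772	bonferroni
12	121317223		121243696	GATC	121186959	bonferroni
13	102408534	102452781	NA	PCCA	102428282	bonferroni
13	111049674	111004953	111035483	NAXD	111060677	bonferroni
15		63345547	63425768	LACTB	63453484	bonferroni
20		25769672	25727136	ACSS1	25740998	bonferroni
22	33046025	33046036	NA	PISD	33058307	bonferroni
2		194739106	194690969	COQ10B	194842026	nominal
2		194739106	194690969	HSPD1	194213959	nominal
2	200305909		200330147	FLJ38973	200457932	nominal
2	200305909		200330147	MAIP1	200070891	nominal
6		76217291	76199095	COX7A2	76466553	nominal
7	48732315	48812202	NA	ABCA13	48628852	nominal
7	140349757	140367908	NA	MRPS33	140378682	nominal
10	112924900	112866891		GPAM	112917454	nominal
11	61284211	61258729	NA	FEN1	61260634	nominal
12	12633435	12621259	NA	HEBP1	12634131	nominal
12	123387213	123750895	123447928	DIABLO	123386662	nominal
12	123387213	123750895	123447928	DIABLO	123386489	nominal
12	123387213	123750895	123447928	ABCB9	123260234	nominal
12	123387213	123750895	123447928	ABCB9	123386756	nominal
12	123387213	123750895	123447928	ABCB9	123386769	nominal
12	123387213	123750895	123447928	COXPD7	123439939	nominal
12	133105848		133168320	PGAM5	133182753	nominal
15	77270791		77310648	IDH3A	77085108	nominal
16	9759261		9794698	ABAT	9799479	nominal
21	44327412	44352930	NA	NDUFV3	44210786	nominal
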