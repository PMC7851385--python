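locus_id	gene_symbol	chrom	start	end	motif	normal_min	normal_max	pathogenic_threshold	threshold_inclusive
HTT	HTT	chr4	3076603	3076660	CAG	6	26	40	1
AR	AR	chrX	66765158	66765227	CAG	9	34	38	1
ATN1	ATN1	chr12	7045879	7045936	CAG	6	35	48	1
ATXN1	ATXN1	chr6	16327865	16327954	CAG	6	38	44	1
ATXN2	ATXN2	chr12	112036753	112036822	CAG	13	31	37	1
ATXN3	ATXN3	chr14	92537354	92537396	CAG	12	44	60	1
CACNA1A	CACNA1A	chr19	13318672	13318711	CAG	4	18	21	1
ATXN7	ATXN7	chr3	63898360	63898390	CAG	4	33	37	1
ATXN8OS	ATXN8OS	chr13	70713162	70713778	CTG	15	44	110	0
ATXN10	ATXN10	chr22	46191234	46191304	ATTCT	10	32	800	1
PPP2R2B	PPP2R2B	chr5	146258290	146258320	CAG	4	32	51	1
TBP	TBP	chr6	170870994	170871105	CAG	25	40	49	1
DMPK	DMPK	chr19	46273174	46273699	CTG	5	35	51	1
CNBP	CNBP	chr3	128891419	128891499	CCTG	11	26	75	1
FMR1	FMR1	chrX	146993568	146993628	CGG	5	44	200	1
AFF2	AFF2	chrX	147582124	147582184	CCG	6	35	200	1
FXN	FXN	chr9	71652202	71652220	GAA	5	33	66	1
C9ORF72	C9orf72	chr9	27573482	27573546	GGGGCC	2	24	60	1
NOP56	NOP56	chr20	2633378	2633402	GGCCTG	3	14	650	1
JPH3	JPH3	chr16	87637893	87637935	CTG	6	28	40	1
PABPN1	PABPN1	chr14	23790681	23790711	GCN	6	10	12	1
HOXD13	HOXD13	chr2	176957786	176957831	GCN	15	15	22	1
HOXA13	HOXA13	chr7	27239481	27239535	GCN	18	18	24	1
RUNX2	RUNX2	chr6	45390419	45390470	GCN	17	17	27	1
ZIC2	ZIC2	chr13	100637703	100637748	GCN	15	15	25	1
ARX	ARX	chrX	25031766	25031814	GCN	16	16	20	1
SOX3	SOX3	chrX	139586481	139586526	GCN	15	15	22	1
PHOX2B	PHOX2B	chr4	41747988	41748048	GCN	20	20	25	1
FOXL2	FOXL2	chr3	138664862	138664904	GCN	14	14	19	1
COMP	COMP	chr19	18896842	18896857	GAC	5	5	6	1
NOTCH2NLC	NOTCH2NLC	chr1	145209323	145209344	GGC	7	40	60	1
GIPC1	GIPC1	chr19	14606940	14606984	CCG	12	32	70	1
LRP12	LRP12	chr8	105601199	105601230	CGG	13	45	90	1
RFC1	RFC1	chr4	39350044	39350099	AAGGG	0	11	400	1
BEAN1	BEAN1	chr16	66524302	66524335	TGGAA	0	10	110	1
DAB1	DAB1	chr1	57832716	57832790	ATTTC	0	16	31	1
SAMD12	SAMD12	chr8	119379052	119379157	TTTCA	0	4	40	1
TNRC6A	TNRC6A	chr16	24624761	24624850	TTTCA	0	4	30	1
RAPGEF2	RAPGEF2	chr4	160263679	160263768	TTTCA	0	4	60	1
MARCHF6	MARCHF6	chr5	10356346	10356411	TTTCA	0	4	30	1
STARD7	STARD7	chr2	96197066	96197121	AAATG	0	4	60	1
YEATS2	YEATS2	chr3	183429976	183430031	TTTCA	0	4	220	1
CSTB	CSTB	chr21	45196324	45196360	CCCCGCCCCGCG	2	3	30	1
TCF4	TCF4	chr18	53253385	53253460	CTG	10	31	50	1
VWA1	VWA1	chr1	1435798	1435818	GGCGCGGAGC	1	1	3	1
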