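# The 23 confirmed large-scale (>100 kb) and interchromosomal structural
# variants of the REH B-cell precursor ALL cell line, with split-read
# (PacBio/ONT) and discordant-mate (Illumina) support per technology.
# called_in: which of the three WGS callsets contained the event.
# size is 0 for interchromosomal breakends (BND).
status	called_in	svtype	chrom1	pos1	chrom2	pos2	size	support_pacbio	support_ont	support_illumina	genes
known	all	INV	chr12	11873746	chr12	96556989	84683243	9	18	16
known	all	BND	chr12	11874372	chr21	34948109	0	6	8	11	ETV6::RUNX1
known	all	BND	chr21	34947932	chr16	90067326	0	19	18	32	RUNX1::PRDM7,CBFA2T3
known	all	BND	chr16	90067537	chr4	159785190	0	5	7	8	PRDM7
known	all	BND	chr4	159785199	chr12	96556785	0	12	17	11
known	all	BND	chr5	128865814	chr12	12123786	0	6	9	16	LRP6::SLC27A6
known	all	BND	chr12	11540006	chr5	126620210	0	13	16	14	PHAX::AC007450.2
known	all	DEL	chr3	35660443	chr3	61437807	25777364	10	16	11	ARPP21,FHIT,SETD2
novel	all	DEL	chr3	177050707	chr3	177196318	145611	12	5	25	TBL1XR1
novel	all	DEL	chr5	143197445	chr5	143402107	204662	7	8	19	NR3C1::ARHGAP26
novel	all	DEL	chr6	111426787	chr6	111563892	137105	11	6	19	TRAF3IP2::REV3L
novel	all	DEL	chr12	91884416	chr12	92144292	259876	12	8	13	BTG1
novel	all	DEL	chr14	72752203	chr14	72892376	140173	11	16	15	DPF3
novel	all	INV	chr16	21583122	chr16	22699431	1116309	13	16	18
novel	all	DEL	chr18	48950471	chr18	49053159	102688	6	9	13	SMAD7
novel	all	DEL	chr18	79384761	chr18	79516951	132190	3	7	10	NFATC1
novel	all	DEL	chr18	75992809	chr18	76208899	216090	9	5	16
novel	all	DEL	chr22	22031472	chr22	22245538	214066	6	9	29	PRAMENP,VPREB1
novel	all	DEL	chr22	22713200	chr22	22904992	191792	5	11	21	IGLL5
novel	ont_pacbio	BND	chr2	89027169	chr1	146784567	0	9	13	5
novel	ont_pacbio	DUP	chr1	103561098	chr1	103676921	115823	9	7	3
novel	ont_illumina	INV	chr2	88861924	chr2	90221383	1359459	7	9	20
novel	illumina	DEL	chr9	20676192	chr9	23121222	2445030	20	19	20	CDKN2A,FOCAD,KLHL9
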