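# The seven manually confirmed expressed fusion genes of the REH cell
# line, ordered 5' -> 3', with short-read (Illumina) and long-read
# (IsoSeq) supporting read counts.
gene5	gene3	sr_reads	lr_reads
ETV6	RUNX1	5	62
RUNX1	PRDM7	144	24
PHAX	AC007450.2	9	5
LRP6	SLC27A6	1	2
BTG1	AC090049.1	120	9
NR3C1	ARHGAP26	10	5
TRAF3IP2	REV3L	6	13
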