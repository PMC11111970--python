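# Genes recurrently altered in B-cell acute lymphoblastic leukemia.
# One symbol per line; replace with any curated list via --genes.
ETV6
RUNX1
PAX5
CDKN2A
CDKN2B
BTG1
NR3C1
TBL1XR1
VPREB1
NFATC1
IGLL5
IKZF1
EBF1
RAG1
RAG2
ERG
TCF3
PBX1
CRLF2
ABL1
ABL2
JAK2
KMT2A
MYC
TP53
RB1
SETD2
FHIT
ARPP21
SMAD7
DPF3
TRAF3IP2
REV3L
LRP6
PHAX
PRDM7
PRDM9
CBFA2T3
PRAME
PRAMENP
ARHGAP26
FOCAD
KLHL9
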