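# KEGG Fanconi anemia pathway (hsa03460) gene membership, 54 genes.
# Reconstructed transcription of the pathway's gene list; one symbol per line.
ATR
ATRIP
BLM
BRCA1
BRCA2
BRIP1
CENPS
CENPX
CHEK1
EME1
EME2
ERCC1
ERCC4
FAAP100
FAAP24
FAN1
FANCA
FANCB
FANCC
FANCD2
FANCE
FANCF
FANCG
FANCI
FANCL
FANCM
HES1
MLH1
MSH2
MSH3
MSH6
MUS81
PALB2
PMS2
POLH
POLI
POLK
POLN
RAD51
RAD51C
REV1
REV3L
RMI1
RMI2
RPA1
RPA2
RPA3
RPA4
SLX4
TOP3A
TOP3B
UBE2T
USP1
WDR48
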