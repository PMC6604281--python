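node_id	class	genes	label
ATR	simple	ATR	ATR damage-sensor kinase
USP1	simple	USP1	USP1 deubiquitinase
Core	complex	FANCM;FANCG;FANCL;FAAP100;FANCA;FANCB;UBE2T;STRA13;FANCC;FAAP24;HES1;FANCE;FANCF;BLM;RMI1;RMI2;TOP3A	FA core complex
FANCD2	simple	FANCD2	FANCD2
FANCI	simple	FANCI	FANCI
SLX4	simple	SLX4	SLX4 nuclease scaffold
ERCC4	simple	ERCC4	ERCC4/XPF endonuclease
MLH1-PMS2	complex	MLH1;PMS2	MutL-alpha mismatch repair complex
REV1	simple	REV1	REV1 translesion polymerase
POLK	simple	POLK	DNA polymerase kappa
REV3L	simple	REV3L	REV3L (pol zeta catalytic subunit)
MAD2L2	simple	MAD2L2	MAD2L2/REV7
FANCC	simple	FANCC	FANCC
FANCA	simple	FANCA	FANCA
BRCA1	simple	BRCA1	BRCA1
BRCA2	simple	BRCA2	BRCA2/FANCD1
PALB2	simple	PALB2	PALB2/FANCN
BRIP1	simple	BRIP1	BRIP1/FANCJ helicase
RAD51	simple	RAD51	RAD51 recombinase
RAD51C	simple	RAD51C	RAD51C paralog
XRCC2	simple	XRCC2	XRCC2 paralog
RFWD3	simple	RFWD3	RFWD3 ubiquitin ligase
RPA	complex	RPA1;RPA2;RPA3;RPA4	RPA single-strand-DNA-binding complex
FANCM-STRA-FAAP24	complex	FANCM;STRA13;FAAP24	FANCM-STRA13-FAAP24 anchoring complex
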