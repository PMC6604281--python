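source	target	sign	provenance	reference
ATR	Core	activation	kegg	hsa03460 backbone (reconstructed)
ATR	FANCM-STRA-FAAP24	activation	kegg	hsa03460 backbone (reconstructed)
Core	FANCD2	activation	kegg	hsa03460 monoubiquitination
Core	FANCI	activation	kegg	hsa03460 monoubiquitination
FANCI	FANCD2	activation	kegg	hsa03460 ID2 complex
USP1	FANCD2	inhibition	kegg	hsa03460 deubiquitination
FANCD2	SLX4	activation	kegg	hsa03460 unhooking branch
SLX4	ERCC4	activation	kegg	hsa03460 unhooking branch
ERCC4	MLH1-PMS2	activation	kegg	hsa03460 mismatch-repair branch
FANCD2	REV1	activation	kegg	hsa03460 translesion branch
REV1	REV3L	activation	kegg	hsa03460 pol-zeta recruitment
FANCD2	PALB2	activation	kegg	hsa03460 homologous-recombination branch
BRCA1	BRCA2	activation	kegg	hsa03460 homologous-recombination branch
BRCA2	RAD51	activation	kegg	hsa03460 filament loading
BRCA1	RAD51C	activation	kegg	hsa03460 paralog branch
FANCD2	RPA	activation	kegg	hsa03460 ssDNA protection
MAD2L2	REV3L	activation	curated	binding;CR37
RFWD3	RPA	activation	curated	binding/association;CR38
XRCC2	RAD51C	activation	curated	activation;CR39
REV1	MAD2L2	activation	curated	binding/association;CR37
FANCC	REV1	activation	curated	activation;CR40
POLK	REV1	activation	curated	binding/association;CR41
BRCA1	REV1	activation	curated	activation;CR42
BRIP1	BRCA1	activation	curated	binding/association;CR43
PALB2	BRCA2	activation	curated	binding/association;CR44
PALB2	BRCA1	activation	curated	binding/association;CR45
FANCA	BRCA1	activation	curated	binding/association;CR46
FANCD2	BRCA1	activation	curated	binding/association;CR47
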