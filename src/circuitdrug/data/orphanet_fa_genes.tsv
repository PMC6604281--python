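symbol	entrez	gene_name
FANCF	2188	Fanconi Anemia complementation group F
FANCC	2176	Fanconi Anemia complementation group C
BRCA2	675	Breast cancer type 2 susceptibility protein
BRCA1	672	Breast cancer type 1 susceptibility protein
FANCE	2178	Fanconi Anemia complementation group E
RAD51	5888	RAD51 recombinase
FANCD2	2177	Fanconi Anemia complementation group D2
FANCM	57697	Fanconi Anemia complementation group M
RAD51C	5889	DNA repair protein RAD51 homolog 3
UBE2T	29089	Ubiquitin-conjugating enzyme E2 T
FANCB	2187	Fanconi Anemia complementation group B
FANCG	2189	Fanconi Anemia complementation group G
FANCI	55215	Fanconi Anemia complementation group I
FANCL	55120	Fanconi Anemia complementation group L
PALB2	79728	partner and localizer of BRCA2
SLX4	84464	SLX4 structure-specific endonuclease subunit
RFWD3	55159	Ring finger and WD repeat domain 3
BRIP1	83990	BRCA1 interacting protein C-terminal helicase 1
ERCC4	2072	ERCC excision repair 4, endonuclease catalytic subunit
MAD2L2	10459	Mitotic arrest deficient 2 like 2
XRCC2	7516	X-ray repair cross complementing 2
FANCA	2175	Fanconi Anemia complementation group A
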