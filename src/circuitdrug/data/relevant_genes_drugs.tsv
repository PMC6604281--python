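gene_name	symbol	entrez	relevance	drug_ids	approved_ids
NIMA related kinase 2	NEK2	4751	0.097324	DB07180;DB12010	DB12010
DNA topoisomerase II alpha	TOP2A	7153	0.078623	DB00276;DB00385;DB00444;DB00694;DB00773;DB00970;DB00997;DB01177;DB01179;DB01204;DB04576;DB04967;DB04975;DB04978;DB05022;DB05706;DB05920;DB06013;DB06263;DB06362;DB06420;DB06421	DB00276;DB00385;DB00444;DB00694;DB00773;DB00970;DB00997;DB01177;DB01179;DB01204
baculoviral IAP repeat containing 5	BIRC5	332	0.052406	DB04115;DB00206;DB05141	DB04115;DB00206
centromere protein E	CENPE	1062	0.036961	DB06097
polo like kinase 1	PLK1	5347	0.036159	DB06897;DB06963;DB07789
cyclin dependent kinase 1	CDK1	983	0.022697	DB05037;DB06195
glutamate ionotropic receptor NMDA type subunit 1	GRIN1	2902	0.019528	DB01931;DB04620;DB05824;DB06741;DB09409;DB09481	DB09409;DB09481
cholinergic receptor nicotinic beta 2 subunit	CHRNB2	1141	0.013228	DB05855
synaptosome associated protein 25	SNAP25	6616	0.012799	DB00083	DB00083
enhancer of zeste 2 polycomb repressive complex 2 subunit	EZH2	2146	0.012543	DB12887;DB14581
methylenetetrahydrofolate dehydrogenase, cyclohydrolase and formyltetrahydrofolate synthetase 1	MTHFD1	4522	0.012111	DB00116;DB02358;DB04322
thymidylate synthetase	TYMS	7298	0.009462	DB00293;DB00322;DB00432;DB00440;DB00544;DB00642;DB01101;DB05116;DB05308;DB05457;DB07577;DB08478;DB08479;DB08734;DB09256	DB00293;DB00322;DB00432;DB00440;DB00544;DB00642;DB01101;DB09256
serpin family E member 1	SERPINE1	5054	0.009206	DB05254
cytochrome c oxidase subunit I	COX1	4512	0.008027	DB09140	DB09140
retinoic acid receptor alpha	RARA	5914	0.007607	DB00523;DB00799;DB00982;DB04942;DB05785	DB00523;DB00799;DB00982
sodium voltage-gated channel alpha subunit 2	SCN2A	6326	0.006728	DB13520
kinesin family member 11	KIF11	3832	0.006366	DB03996;DB04331;DB06040;DB07064;DB08032;DB08033;DB08037;DB08198;DB08239;DB08244;DB08246;DB08250
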