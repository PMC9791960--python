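domain_type	genes	gene_number	chr	genomes
PHD	TaPHD1/TaPHD8/TaPHD15	3	1	ABD
PHD	TaPHD5/TaPHD12	2	1	AB
PHD	TaPHD21/TaPHD34/TaPHD46	3	2	ABD
PHD	TaPHD62/TaPHD73/TaPHD84	3	3	ABD
PHD	TaPHD82	1	3	D
PHD	TaPHD94/TaPHD114/TaPHD128	3	4	ABD
PHD	TaPHD218/TaPHD226/TaPHD237	3	7	ABD
PHD	TaPHD98/TaPHD110/TaPHD124	3	4	ABD
PHD	TaPHD99/TaPHD109/TaPHD123	3	4	ABD
PHD	TaPHD101/TaPHD107/TaPHD121	3	4	ABD
PHD	TaPHD143/TaPHD160/TaPHD177	3	5	ABD
PHD	TaPHD103	1	4	A
PHD	TaPHD137/TaPHD154/TaPHD172	3	5	ABD
PHD	TaPHD146/TaPHD163/TaPHD180	3	5	ABD
PHD	TaPHD168/TaPHD185	2	5	BD
PHD	TaPHD186	1	5	D
PHD	TaPHD192/TaPHD201/TaPHD209	3	6	ABD
PHD-PHD	TaPHD135/TaPHD152/TaPHD170	3	5	ABD
PHD-PHD	TaPHD144/TaPHD161/TaPHD178	3	5	ABD
PHD-PHD	TaPHD216/TaPHD224/TaPHD235	3	7	ABD
Alifn-PHD	TaPHD4/TaPHD11/TaPHD18	3	1	ABD
Alifn-PHD	TaPHD6/TaPHD13/TaPHD19	3	1	ABD
Alifn-PHD	TaPHD26/TaPHD39/TaPHD51	3	2	ABD
Alifn-PHD	TaPHD31/TaPHD44/TaPHD56	3	2	ABD
Alifn-PHD	TaPHD64/TaPHD75/TaPHD86	3	3	ABD
Alifn-PHD	TaPHD100/TaPHD108/TaPHD122	3	4	ABD
Alifn-PHD	TaPHD167/TaPHD184	2	5	BD
Alifn-PHD	TaPHD104/TaPHD229/TaPHD230/TaPHD243/TaPHD244	5	4(7)	A(DD)UU
ARID-PHD	TaPHD142/TaPHD159/TaPHD176	3	5	ABD
RING-PHD	TaPHD23/TaPHD36/TaPHD48	3	2	ABD
RING-PHD	TaPHD93/TaPHD115/TaPHD129	3	4	ABD
ING-PHD	TaPHD105/TaPHD119/TaPHD133	3	4	ABD
ING-PHD	TaPHD148/TaPHD165/TaPHD182	3	5	ABD
BAH-PHD	TaPHD27/TaPHD40/TaPHD53	3	2	ABD
BAH-PHD	TaPHD141/TaPHD158/TaPHD175	3	5	ABD
BAH-PHD	TaPHD149/TaPHD166/TaPHD183	3	5	ABD
Jas-PHD	TaPHD28/TaPHD41/TaPHD52	3	2	ABD
Jas-PHD	TaPHD147/TaPHD164/TaPHD181	3	5	ABD
Jas-PHD	TaPHD30/TaPHD43/TaPHD55	3	2	ABD
Jas-PHD	TaPHD33/TaPHD45/TaPHD58	3	2	ABD
Jas-PHD	TaPHD22/TaPHD35/TaPHD47	3	2	ABD
Jas-PHD	TaPHD92/TaPHD116/TaPHD130	3	4	ABD
Jas-PHD	TaPHD66/TaPHD76/TaPHD88	3	3	ABD
Jas-PHD	TaPHD68/TaPHD78	2	3	AB
Jas-PHD	TaPHD106/TaPHD212	2	4(7)	A(A)
Jas-PHD	TaPHD220/TaPHD227/TaPHD238	3	7	ABD
DDT-PHD	TaPHD25/TaPHD38/TaPHD50	3	2	ABD
DDT-PHD	TaPHD97/TaPHD112/TaPHD125	3	4	ABD
DDT-PHD	TaPHD138/TaPHD155/TaPHD173	3	5	ABD
zf-HC5HC2H-PHD	TaPHD59/TaPHD70/TaPHD80	3	3	ABD
PHD-Oberon_cc	TaPHD91/TaPHD118/TaPHD132	3	4	ABD
PHD-Oberon_cc	TaPHD95/TaPHD111/TaPHD127	3	4	ABD
PHD-Oberon_cc	TaPHD136/TaPHD153/TaPHD171	3	5	ABD
PHD-Oberon_cc	TaPHD117/TaPHD131	2	4	BD
PHD-FN3	TaPHD3/TaPHD10/TaPHD17	3	1	ABD
PHD-FN3	TaPHD134/TaPHD151/TaPHD169	3	5	ABD
PHD-FN3	TaPHD190/TaPHD199/TaPHD207	3	6	ABD
PHD-SANT	TaPHD63/TaPHD74/TaPHD85	3	3	ABD
PHD-SANT	TaPHD194/TaPHD203/TaPHD211	3	6	ABD
PHD-WHIM1	TaPHD102/TaPHD191/TaPHD200/TaPHD208	4	6(4)	(A)ABD
PHD-SET	TaPHD67/TaPHD77/TaPHD89	3	3	ABD
PHD-SET	TaPHD187/TaPHD196/TaPHD242	3	6	AB(U)
PWWP-PHD-SET	TaPHD60/TaPHD71/TaPHD81	3	3	ABD
PWWP-FYRN-FYRC-PHD-SET	TaPHD140/TaPHD157/TaPHD174	3	5	ABD
PHD-BAH	TaPHD234	1	7	D
PHD-BAH-AAA	TaPHD214/TaPHD222/TaPHD232	3	7	ABD
PHD-homeodomain	TaPHD7/TaPHD14/TaPHD20	3	1	ABD
PHD-homeodomain	TaPHD61/TaPHD72/TaPHD83	3	3	ABD
PHD-homeodomain	TaPHD189/TaPHD198/TaPHD206	3	6	ABD
PHD-PLN03142	TaPHD65/TaPHD87	2	3	AD
PHD-PLN03142	TaPHD195/TaPHD204/TaPHD241	3	6	ABD
PHD-RING	TaPHD2/TaPHD9/TaPHD16	3	1	ABD
PHD-RING	TaPHD69/TaPHD79/TaPHD90	3	3	ABD
PHD-RING	TaPHD96/TaPHD113/TaPHD126	3	4	ABD
PHD-RING	TaPHD139/TaPHD156	2	5	AB
PHD-JmjC-PLU1	TaPHD219/TaPHD228/TaPHD239	3	7	ABD
AAA_34-PHD-Helicase_C_4	TaPHD32/TaPHD57	2	2	AD
AAA_34-PHD-Helicase_C_4	TaPHD217/TaPHD225/TaPHD236	3	7	ABD
PHD-zf-HC5HC2H-zf-HC5HC2H	TaPHD193/TaPHD202/TaPHD210	3	6	ABD
PHD-zf-HC5HC2H-zf-HC5HC2H	TaPHD215/TaPHD223/TaPHD233	3	7	ABD
BRCT-BRCT-PHD	TaPHD24/TaPHD37/TaPHD49	3	2	ABD
BRCT-BRCT-PHD	TaPHD188/TaPHD197/TaPHD205	3	6	ABD
PHD-SWIB-GYF-Plus3	TaPHD120/TaPHD150/TaPHD240	3	4(5)	(A)BU
PHD-SWIB-Plus3-GYF	TaPHD145/TaPHD162/TaPHD179	3	5	ABD
PHD-Chromo-Helicase_C-DUF	TaPHD213/TaPHD221/TaPHD231	3	7	ABD
PHD-Cohesin_HEAT-Nipped-B_C	TaPHD29/TaPHD42/TaPHD54	3	2	ABD
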