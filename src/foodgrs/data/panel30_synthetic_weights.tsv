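rsid	risk_allele	other_allele	beta_speliotes	beta_finhit	gene
rs11165643	T	C	0.06	0.06	PTBP2
rs1514175	A	G	0.07	0.07	TNNI3K
rs2815752	A	G	0.13	0.13	NEGR1
rs543874	G	A	0.22	0.22	SEC16B
rs11676272	G	A	0.14	0.14	RBJ
rs2121279	T	C	0.08	0.08	LRP1B
rs2867125	C	T	0.31	0.31	TMEM18
rs887912	T	C	0.10	0.10	FANCL
rs13078807	G	A	0.10	0.10	CADM2
rs7647305	C	T	0.14	0.14	ETV5
rs10938397	G	A	0.18	0.18	GNPDA2
rs13107325	T	C	0.19	0.19	SLC39A8
rs2112347	T	G	0.10	0.10	FLJ35779
rs206936	G	A	0.06	0.06	NUDT3
rs987237	G	A	0.13	0.13	TFAP2B
rs10968576	G	A	0.11	0.11	LRRN6C
rs2030323	C	A	0.19	0.19	BDNF
rs3817334	T	C	0.06	0.06	MTCH2
rs7127684	T	C	0.06	0.06	RPL27A
rs7138803	A	G	0.12	0.12	FAIM2
rs10134820	T	C	0.07	0.07	PRKD1
rs17109256	T	C	0.13	0.13	NRXN3
rs2241423	G	A	0.13	0.13	MAP2K5
rs12444979	C	T	0.17	0.17	GPRC5B
rs1421085	C	T	0.39	0.39	FTO
rs7359397	T	C	0.15	0.15	SH2B1
rs571312	A	C	0.23	0.23	MC4R
rs2287019	C	T	0.15	0.15	QPCTL
rs29941	G	A	0.06	0.06	KCTD15
rs3810291	A	G	0.09	0.09	TMEM160
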