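enzyme_action	gene_name	gene_symbol	ncbi_gene_id
DNA methylation	DNA methyltransferase 1	DNMT1	1786
DNA methylation	DNA methyltransferase 3 alpha	DNMT3A	1788
DNA methylation	DNA methyltransferase 3 beta	DNMT3B	1789
DNA methylation	Trna aspartic acid methyltransferase 1	TRDMT1	1787
DNA demethylation	Alkb homolog 2, alpha-ketoglutarate dependent dioxygenase	ALKBH2	121642
DNA demethylation	Alkb homolog 3, alpha-ketoglutarate dependent dioxygenase	ALKBH3	221120
DNA demethylation	FTO alpha-ketoglutarate dependent dioxygenase	FTO	79068
DNA demethylation	Apolipoprotein B mrna editing enzyme catalytic subunit 1	APOBEC1	339
histone methylation	Enhancer of zeste 1 polycomb repressive complex 2 subunit	EZH1	2145
histone methylation	Enhancer of zeste 2 polycomb repressive complex 2 subunit	EZH2	2146
histone demethylation	Lysine demethylase 5D	KDM5D	8284
histone acetylation	Lysine acetyltransferase 2A	KAT2A	2648
histone acetylation	Lysine acetyltransferase 2B	KAT2B	8850
histone acetylation	Lysine acetyltransferase 5	KAT5	10524
histone acetylation	Nuclear receptor coactivator 1	NCOA1	8648
histone acetylation	Nuclear receptor coactivator 2	NCOA2	10499
histone deacetylation	Histone deacetylase 1	HDAC1	3065
histone deacetylation	Histone deacetylase 10	HDAC10	83933
histone deacetylation	Histone deacetylase 2	HDAC2	3066
histone deacetylation	Histone deacetylase 3	HDAC3	8841
histone deacetylation	Histone deacetylase 4	HDAC4	9759
histone deacetylation	Histone deacetylase 6	HDAC6	10013
histone deacetylation	Histone deacetylase 8	HDAC8	55869
histone deacetylation	Histone deacetylase 9	HDAC9	9734
histone deacetylation	Sirtuin 1	SIRT1	23411
histone deacetylation	Sirtuin 5	SIRT5	23408
histone ubiquitination	MDM2 proto-oncogene	MDM2	4193
histone ubiquitination	Ubiquitin like modifier activating enzyme 1	UBA1	7317
histone deubiquitination	BRCA1/BRCA2-containing complex subunit 3	BRCC3	79184
histone phosphorylation	Protein kinase AMP-activated catalytic subunit alpha 1	PRKAA1	5562
histone phosphorylation	Protein kinase AMP-activated non-catalytic subunit beta 1	PRKAB1	5564
histone phosphorylation	Cyclin dependent kinase 17	CDK17	5128
histone phosphorylation	Cyclin dependent kinase 2	CDK2	1017
histone phosphorylation	Cyclin dependent kinase 5	CDK5	1020
histone phosphorylation	Cyclin dependent kinase 8	CDK8	1024
histone phosphorylation	Death associated protein kinase 3	DAPK3	1613
histone phosphorylation	Protein kinase, DNA-activated, catalytic subunit	PRKDC	5591
histone phosphorylation	Glycogen synthase kinase 3 beta	GSK3B	2932
histone phosphorylation	Component of inhibitor of nuclear factor kappa B kinase complex	CHUK	1147
histone phosphorylation	LIM domain kinase 2	LIMK2	3985
histone phosphorylation	Mitogen-activated protein kinase kinase kinase 12	MAP3K12	7786
histone phosphorylation	Mitogen-activated protein kinase kinase kinase 20	MAP3K20	51776
histone phosphorylation	Protein kinase C alpha	PRKCA	5578
histone phosphorylation	Protein kinase C beta	PRKCB	5579
histone phosphorylation	Ribosomal protein S6 kinase A3	RPS6KA3	6197
histone phosphorylation	Ribosomal protein S6 kinase A4	RPS6KA4	8986
histone phosphorylation	ATM serine/threonine kinase	ATM	472
histone phosphorylation	Serine/threonine kinase 10	STK10	6793
histone phosphorylation	Aurora kinase B	AURKB	9212
histone phosphorylation	Aurora kinase C	AURKC	6795
histone phosphorylation	Aurora kinase A	AURKA	6790
histone phosphorylation	Checkpoint kinase 1	CHEK1	1111
histone phosphorylation	Protein kinase N1	PKN1	5585
histone phosphorylation	NIMA related kinase 9	NEK9	91754
histone phosphorylation	P21 (RAC1) activated kinase 1	PAK1	5058
histone phosphorylation	P21 (RAC1) activated kinase 2	PAK2	5062
histone phosphorylation	Tousled like kinase 1	TLK1	9874
histone phosphorylation	FYN proto-oncogene, Src family tyrosine kinase	FYN	2534
histone phosphorylation	Janus kinase 2	JAK2	3717
histone dephosphorylation	Protein phosphatase 2 catalytic subunit alpha	PPP2CA	5515
histone dephosphorylation	Protein phosphatase 2 catalytic subunit beta	PPP2CB	5516
histone dephosphorylation	Protein phosphatase 5 catalytic subunit	PPP5C	5536
histone ADP-ribosylation	Poly(ADP-ribose) polymerase 1	PARP1	142
histone ADP-ribosylation	Poly(ADP-ribose) polymerase 2	PARP2	10038
histone ADP-ribosylation	Poly(ADP-ribose) polymerase family member 3	PARP3	10039
histone de-ADP-ribosylation	*O*-glcnacase	OGA	10724
histone citrullination	Peptidyl arginine deiminase 1	PADI4	29943
histone biotinylation	Holocarboxylase synthetase	HLCS	3141
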