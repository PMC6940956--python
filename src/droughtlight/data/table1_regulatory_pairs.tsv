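tf_gene	tf_fold_change	tf_fdr	tf_family	tf_description	target_gene	target_description	target_fold_change	target_fdr
HORVU4Hr1G078410	-20.36	2.25e-15	HD-ZIP	Homeobox-leucine zipper protein family	HORVU2Hr1G010630	ribulose-bisphosphate carboxylase small chain [EC:4.1.1.39]	-432.2	1.56e-4
HORVU1Hr1G073300	-12.71	7.62e-5	MYB_related	myb-like transcription factor family protein	HORVU1Hr1G035720	ribulose-bisphosphate carboxylase small chain [EC:4.1.1.39]	-37.5	1.26e-84
HORVU6Hr1G066000	-8.18	9.07e-5	MYB_related	myb-like transcription factor family protein	HORVU1Hr1G067300	phosphoglycerate kinase [EC:2.7.2.3]	-52.7	2.27e-32
HORVU6Hr1G019650	-7.20	8.16e-6	G2-like	myb-like transcription factor family protein	HORVU5Hr1G109260	light-harvesting complex II chlorophyll a/b binding protein 1	-1357	5.10e-37
HORVU5Hr1G014170	-5.41	5.13e-4	bZIP	Basic-leucine zipper (bZIP) transcription factor family protein	HORVU2Hr1G060480	photosystem I subunit X	-54.7	2.56e-27
HORVU3Hr1G088200	-3.78	3.03e-3	WRKY	WRKY DNA-binding protein 33	HORVU5Hr1G087250	light-harvesting complex II chlorophyll a/b binding protein 1	-13.1	1.86e-6
HORVU3Hr1G032440	-3.26	8.28e-4	G2-like	Two-component response regulator-like APRR2	HORVU2Hr1G075200	F-type H+-transporting ATPase subunit b	-52.7	2.84e-16
HORVU2Hr1G060680	-2.62	6.33e-4	bHLH	Transcription factor PIF5	HORVU6Hr1G033160	light-harvesting complex I chlorophyll a/b binding protein 3	-30.2	5.16e-11
HORVU6Hr1G074970	-2.37	2.93e-3	ERF	Ethylene-responsive transcription factor 1	HORVU3Hr1G013350	triosephosphate isomerase (TIM) [EC:5.3.1.1]	-6.7	8.10e-16
HORVU4Hr1G052330	2.46	3.42e-3	bZIP	transcription factor-related	HORVU2Hr1G063740	glutamate--glyoxylate aminotransferase [EC:2.6.1.4 2.6.1.2 2.6.1.44]	-8.0	2.03e-11
HORVU1Hr1G074960	2.80	4.37e-8	bZIP	G-box binding factor 4	HORVU1Hr1G021830	cytochrome b6-f complex subunit 4	-4.3	1.49e-3
HORVU5Hr1G036330	3.05	7.45e-4	GATA	GATA transcription factor 9	HORVU6Hr1G051650	photosystem II oxygen-evolving enhancer protein 3	-202.0	7.00e-4
HORVU1Hr1G090030	3.06	8.67e-8	bZIP	G-box binding factor 2	HORVU2Hr1G062090	cytochrome b6	-6.7	6.65e-9
HORVU4Hr1G020540	3.12	2.20e-4	bZIP	Transcription factor VIP1	HORVU2Hr1G043240	photosystem II P680 reaction center D1 protein [EC:1.10.3.9]	-5.9	5.99e-13
HORVU2Hr1G119610	3.53	4.62e-4	MYB_related	myb-like transcription factor family protein	HORVU2Hr1G043240	photosystem II P680 reaction center D1 protein [EC:1.10.3.9]	-5.9	5.99e-13
HORVU4Hr1G051290	10.72	1.46e-9	NAC	NAC domain protein.	HORVU6Hr1G037020	photosystem I P700 chlorophyll a apoprotein A1	-5.9	4.15e-7
HORVU2Hr1G021080	13.16	5.84e-7	bZIP	Basic-leucine zipper (bZIP) transcription factor family protein	HORVU2Hr1G062090	cytochrome b6	-6.7	6.65e-9
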