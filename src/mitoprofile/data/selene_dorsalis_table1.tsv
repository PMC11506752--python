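gene	kind	start	stop	strand	anticodon
tRNA-Phe	tRNA	1	68	+	GAA
12S-rRNA	rRNA	68	1022	+	.
tRNA-Val	tRNA	1022	1094	+	TAC
16S-rRNA	rRNA	1095	2809	+	.
tRNA-Leu(L2)	tRNA	2809	2883	+	TAA
ND1	PCG	2884	3858	+	.
tRNA-Ile	tRNA	3863	3933	+	GAT
tRNA-Gln	tRNA	3932	4003	-	TTG
tRNA-Met	tRNA	4002	4072	+	CAT
ND2	PCG	4073	5117	+	.
tRNA-Trp	tRNA	5117	5188	+	TCA
tRNA-Ala	tRNA	5189	5258	-	TGC
tRNA-Asn	tRNA	5259	5332	-	GTT
tRNA-Cys	tRNA	5370	5437	-	GCA
tRNA-Tyr	tRNA	5437	5507	-	GTA
COI	PCG	5509	7059	+	.
tRNA-Ser(S2)	tRNA	7059	7130	-	TGA
tRNA-Asp	tRNA	7133	7203	+	GTC
COII	PCG	7211	7901	+	.
tRNA-Lys	tRNA	7901	7976	+	TTT
ATP8	PCG	7978	8145	+	.
ATP6	PCG	8136	8818	+	.
COIII	PCG	8819	9603	+	.
tRNA-Gly	tRNA	9603	9673	+	TCC
ND3	PCG	9674	10022	+	.
tRNA-Arg	tRNA	10022	10091	+	TCG
ND4L	PCG	10093	10389	+	.
ND4	PCG	10383	11763	+	.
tRNA-His	tRNA	11763	11835	+	GTG
tRNA-Ser(S1)	tRNA	11835	11903	+	GCT
tRNA-Leu(L1)	tRNA	11909	11982	+	TAG
ND5	PCG	11983	13821	+	.
ND6	PCG	13818	14339	-	.
tRNA-Glu	tRNA	14339	14408	-	TTC
CYTB	PCG	14412	15552	+	.
tRNA-Thr	tRNA	15552	15624	+	TGT
tRNA-Pro	tRNA	15623	15694	-	TGG
CR	CR	15695	16541	+	.
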