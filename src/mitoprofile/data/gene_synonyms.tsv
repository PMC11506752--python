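alias	canonical
COX1	COI
COX2	COII
COX3	COIII
CO1	COI
CO2	COII
CO3	COIII
COXI	COI
COXII	COII
COXIII	COIII
MT-CO1	COI
MT-CO2	COII
MT-CO3	COIII
CYB	CYTB
COB	CYTB
MT-CYB	CYTB
ATPASE6	ATP6
ATPASE8	ATP8
ATP SYNTHASE F0 SUBUNIT 6	ATP6
ATP SYNTHASE F0 SUBUNIT 8	ATP8
MT-ATP6	ATP6
MT-ATP8	ATP8
NAD1	ND1
NAD2	ND2
NAD3	ND3
NAD4	ND4
NAD4L	ND4L
NAD5	ND5
NAD6	ND6
MT-ND1	ND1
MT-ND2	ND2
MT-ND3	ND3
MT-ND4	ND4
MT-ND4L	ND4L
MT-ND5	ND5
MT-ND6	ND6
12S RIBOSOMAL RNA	12S-rRNA
16S RIBOSOMAL RNA	16S-rRNA
S-RRNA	12S-rRNA
L-RRNA	16S-rRNA
RRNS	12S-rRNA
RRNL	16S-rRNA
12S RRNA	12S-rRNA
16S RRNA	16S-rRNA
D-LOOP	CR
CONTROL REGION	CR
TRNA-SER1	tRNA-Ser(S1)
TRNA-SER2	tRNA-Ser(S2)
TRNA-LEU1	tRNA-Leu(L1)
TRNA-LEU2	tRNA-Leu(L2)
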