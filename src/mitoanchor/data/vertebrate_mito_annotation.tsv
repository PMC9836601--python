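#genome_id=vertebrate_mito_reference
#genome_length=16569
name	type	start	end	strand
tRNA-Phe	tRNA	577	647	+
rRNA-12S	rRNA	648	1601	+
tRNA-Val	tRNA	1602	1670	+
rRNA-16S	rRNA	1671	3229	+
tRNA-Leu(UUR)	tRNA	3230	3304	+
ND1	CDS	3307	4262	+
tRNA-Ile	tRNA	4263	4331	+
tRNA-Gln	tRNA	4329	4400	-
tRNA-Met	tRNA	4402	4469	+
ND2	CDS	4470	5511	+
tRNA-Trp	tRNA	5512	5579	+
tRNA-Ala	tRNA	5587	5655	-
tRNA-Asn	tRNA	5657	5729	-
tRNA-Cys	tRNA	5761	5826	-
tRNA-Tyr	tRNA	5826	5891	-
COX1	CDS	5904	7445	+
tRNA-Ser(UCN)	tRNA	7446	7514	-
tRNA-Asp	tRNA	7518	7585	+
COX2	CDS	7586	8269	+
tRNA-Lys	tRNA	8295	8364	+
ATP8	CDS	8366	8572	+
ATP6	CDS	8527	9207	+
COX3	CDS	9207	9990	+
tRNA-Gly	tRNA	9991	10058	+
ND3	CDS	10059	10404	+
tRNA-Arg	tRNA	10405	10469	+
ND4L	CDS	10470	10766	+
ND4	CDS	10760	12137	+
tRNA-His	tRNA	12138	12206	+
tRNA-Ser(AGY)	tRNA	12207	12265	+
tRNA-Leu(CUN)	tRNA	12266	12336	+
ND5	CDS	12337	14148	+
ND6	CDS	14149	14673	-
tRNA-Glu	tRNA	14674	14742	-
CYTB	CDS	14747	15887	+
tRNA-Thr	tRNA	15888	15953	+
tRNA-Pro	tRNA	15956	16023	-
D-loop	D-loop	16024	16569	+
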