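# Published excerpt of the tammar wallaby chromosome 5 integrated/virtual
# map: locus, external annotation id, kb, confidence level, cM, band.
# Confidence: 2 = mapped in wallaby, 1 = interpolated in an oriented block,
# 0 = interpolated in an unoriented block, NA = landmark/breakpoint.
# locus	external_id	kb	confidence	cm	band
ptr	-	0	NA	0.00	p3
MAP3K15	ENSMODG00000009020	52	2	0.04	p3
CXADR	ENSMODG00000020956	36862	2	29.53	p2
USP25	ENSMODG00000020954	37113	1	29.73	p2
NRIP1	ENSMODG00000020951	37474	1	30.02	p2
SAMSN1	ENSMODG00000020950	37623	2	30.14	p2
BREAKPOINT1	-	37729	NA	30.22	p2
RPL31	-	37869	NA	30.34	p2
EGFL6	-	65104	NA	52.15	p1
cen	-	66812	NA	53.52	cen
ASB9	ENSMODG00000017264	66989	1	53.64	q1
PIGA	ENSMODG00000017236	67096	1	53.71	q1
CTPS2	ENSMODG00000017176	68521	2	54.64	q1
CPOX	-	71284	NA	56.45	q1
BREAKPOINT2	-	71500	NA	56.59	q1
ALCAM	-	74180	NA	58.35	q1
ZEB2	-	141002	NA	102.18	q2
BREAKPOINT3	-	152272	NA	109.57	q2
TECTA	-	154477	NA	111.01	q2
KJW192	-	202612	NA	142.58	q2
BREAKPOINT4	-	206066	NA	144.85	q2
SPG20	-	207288	NA	145.65	q2
BACE1	-	264904	NA	183.44	q2
BREAKPOINT5	-	267109	NA	184.88	q2
HPX	-	268326	NA	185.68	q2
PHCA	-	287618	NA	198.34	q2
BREAKPOINT6	-	291421	NA	200.83	q2
CCKBR	-	292596	NA	201.60	q2
RRM1	-	292596	NA	201.60	q3
BREAKPOINT7	-	293771	NA	202.37	q3
MORN1	ENSG00000116151	293771	0	202.37	q3
PANK4	ENSG00000157881	293913	0	202.46	q3
DFFB	ENSG00000169598	294925	2	203.13	q3
LEPRE1	-	324670	NA	222.64	q3
BREAKPOINT8	-	324806	NA	222.73	q3
BCL3	-	332209	NA	227.58	q3
LENG8	ENSG00000167615	339572	2	232.41	q3
LENG9	ENSG00000182909	339581	0	232.42	q3
qtr	-	340000	NA	232.68	qtr
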