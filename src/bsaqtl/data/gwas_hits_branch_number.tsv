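qtl	snp_id	chrom	pos	p_value	r2	alleles	year	model
qGBN1	S01_647060	1	37500028	4.69e-7	11.65	C/T	2022	MLM
qGBN1	S01_647058	1	37499994	4.79e-6	9.82	T/C	2022	MLM
qGBN2	S11_383602	1	20996571	5.00e-6	9.51	T/A	2022	BLINK
qGBN3	S02_1240704	2	12264757	6.94e-14	27.18	A/G	2022	BLINK
qGBN3	S02_1241353	2	12324064	1.87e-8	14.17	C/T	2022	BLINK
qGBN3	S02_1240704	2	12264757	2.99e-6	9.77		2022	MLM
qGBN3	S02_1240704	2	12264757	5.56e-6	9.32		2023	MLM
qGBN3	S02_1240704	2	12264757	8.57e-6	9.25		2023	BLINK
qGBN4	S05_3893779	5	11122603	5.02e-6	9.55	T/C	2023	BLINK
qGBN4	S05_3893779	5	11122603	8.31e-6	9.27		2023	MLM
qGBN5	S06_4772142	6	23576358	6.07e-6	9.66	C/A	2023	BLINK
qGBN6	S06_5137235	6	44380411	8.54e-6	9.25	G/A	2022	BLINK
qGBN7	S10_8203320	10	33337627	9.46e-9	14.86	G/T	2023	BLINK
qGBN8	S10_7804544	10	8551686	5.73e-6	9.30	A/T	2022	BLINK
qGBN9	S11_8849037	11	22593147	2.81e-9	15.85	T/A	2022	BLINK
qGBN10	S12_9388376	12	13737593	3.51e-7	12.17	C/T	2022	BLINK
qGBN11	S13_10274380	13	21682594	4.83e-6	9.82	G/A	2022	BLINK
qGBN12	S14_10921879	14	13946264	9.64e-6	9.25	G/A	2022	BLINK
qGBN13	S15_12533199	15	50770118	9.67e-6	9.16	A/G	2022	BLINK
qGBN14	S16_12903158	16	16529439	3.82e-6	10.02	G/C	2022	BLINK
qGBN15	S17_13967003	17	35344266	7.99e-6	9.27	C/A	2022	BLINK
qGBN16	S18_14535964	18	20984058	5.30e-6	9.51	A/G	2022	BLINK
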