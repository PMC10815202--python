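qtl	chrom	start	end	peak	method
qBBN1	Gm02	11420001	15020000	0.559684	ed
qBBN1	Gm02	11440001	15070000	22.53829	g
qBBN1	Gm02	11530001	15020000	0.517047	delta
qBBN1	Gm02	12280001	13360000	0.003283	fisher
qBBN2	Gm05	8580001	10660000	11.91817	g
qBBN2	Gm05	9270001	10430000	0.340816	ed
qBBN3	Gm05	11450001	12970000	11.65613	g
qBBN3	Gm05	11460001	12850000	0.348614	ed
qBBN3	Gm05	11570001	12570000	-0.37708	delta
qBBN4	Gm05	16210001	18710000	11.9553	g
qBBN4	Gm05	16210001	18940000	0.411016	ed
qBBN4	Gm05	16210001	18910000	-0.4334	delta
qBBN5	Gm05	22600001	23850000	-0.37968	delta
qBBN5	Gm05	22830001	23880000	0.329834	ed
qBBN6	Gm05	25240001	27230000	0.383032	ed
qBBN6	Gm05	25740001	26750000	-0.39135	delta
qBBN6	Gm05	26070001	27230000	10.96294	g
qBBN7	Gm05	27540001	29280000	0.374127	ed
qBBN7	Gm05	27850001	29330000	13.24474	g
qBBN7	Gm05	27850001	29220000	-0.41289	delta
qBBN8	Gm06	47020001	48270000	11.02317	g
qBBN8	Gm06	47060001	48240000	0.326973	ed
qBBN9	Gm13	43170001	44200000	0.325159	ed
qBBN10	Gm15	44910001	46480000	11.18481	g
qBBN11	Gm15	51360001	53140000	13.02159	g
qBBN12	Gm16	32020001	33890000	0.324992	ed
qBBN12	Gm16	32490001	34130000	10.81712	g
qBBN13	Gm16	36050001	37470000	0.35877	ed
qBBN13	Gm16	36170001	37440000	11.15172	g
qBBN14	Gm20	19840001	20840000	-0.38348	delta
qBBN15	Gm20	23160001	25850000	0.361823	ed
qBBN15	Gm20	23330001	24470000	10.97986	g
qBBN16	Gm20	24620001	25850000	11.71612	g
qBBN16	Gm20	24620001	25660000	-0.39685	delta
qBBN17	Gm20	25860001	27730000	0.381719	ed
qBBN17	Gm20	26020001	27610000	13.35137	g
qBBN17	Gm20	26170001	27320000	-0.39762	delta
qBBN18	Gm20	31420001	32420000	11.04967	g
qBBN18	Gm20	31420001	32420000	0.341994	ed
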