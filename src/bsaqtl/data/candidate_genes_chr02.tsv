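gene_id	chrom	start	end	symbol	annotation
Glyma.02G125100	Gm02	12220107	12224403	SRG1	2-oxoglutarate/Fe(II)-dependent dioxygenase-like
Glyma.02G125200	Gm02	12226179	12230868	BHLH49	Transcription factor bHLH49 isoform X1
Glyma.02G125300	Gm02	12229902	12230859
Glyma.02G125400	Gm02	12246600	12253822	WIT2	WPP domain-interacting tail-anchored protein 2-like isoform X4
Glyma.02G125500	Gm02	12268030	12268302
Glyma.02G125551	Gm02	12279258	12279410
Glyma.02G125600	Gm02	12302237	12304986	GH3.1	Indole-3-acetic acid-amido synthetase GH3.1
Glyma.02G125700	Gm02	12306697	12309236
Glyma.02G125800	Gm02	12314438	12315067
Glyma.02G125900	Gm02	12317269	12318465
Glyma.02G126000	Gm02	12321542	12323547	IRT2	Fe(2+) transport protein 1
Glyma.02G126100	Gm02	12368440	12371047	BZIP43	Basic leucine zipper transcription factor-like protein
Glyma.02G126200	Gm02	12375750	12376682
Glyma.02G126300	Gm02	12388195	12394795	CPN60B4	RuBisco large subunit-binding protein subunit beta
Glyma.02G126500	Gm02	12412320	12413154	SNAT2	Serotonin N-acetyltransferase 2, chloroplastic
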