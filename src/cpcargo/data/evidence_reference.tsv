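accession	chloroplast	mitochondrion	secretory	tools	proteomics_msms	chloroplast2010	tair
At3g52190	7.6	0	0.3	MultiLoc;PCLR;SLPFA;TargetP	.	1	ER, PM
At1g72150	2.3	0	0	.	chloroplast	1	Chl., PM, Vacuole
At4g09160	4.7	0	0	TargetP	chloroplast	1	Chl.
At1g22530	3.1	0	0	.	chloroplast	1	Chl., PM
At5g63060	18.1	4.2	0.4	.	chloroplast	1	Chl.
At2g16380	5.2	0	0	ChloroP;PCLR;PredSL	.	.	.
At3g46450	6.7	4.2	0	ChloroP;PCLR;PProwler;WoLFPSORT	.	.	.
At2g18180	5	0	2.7	BacelLo;MultiLoc;PredSL;Plant-mPloc;TargetP	.	1	.
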