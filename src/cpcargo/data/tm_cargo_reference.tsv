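accession	name	section	motifs	tm_spans	orientation
At1g02910	AtLPA1	diacidic	EEE,DFD,EIE	2	N(In)-C(In)
At1g03160	AtFZL	diacidic	DID	2	N(In)-C(In)
At1g15820	AtLHCb6/AtCP24	diacidic	EPD,DFD	2	N(In)-C(In)
At1g18730	AtNDF6	diacidic	DIE,EIE	1	N(Out)-C(In)/N(In)-C(Out)
At1g34000	AtOHP2	diacidic	DLE	2	N(In)-C(In)
At1g44575	AtPsbS	diacidic	DGE	4	N(In)-C(In)
At2g18710	AtSCY1	diacidic	ELD	10	N(In)-C(In)
At2g26500	Cyt b6f subunit IV	diacidic	EAE,EAE	1	N(Out)-C(In)
At2g28800	AtAlb3	diacidic	EQE,ESE,DDEEEE	4	N(In)-C(In)/N(Out)-C(Out)
At2g30570	AtPsbW	diacidic	EEDEE	2	N(In)-C(In)
At3g08940	AtLHCb4.2	diacidic	DID	2	N(In)-C(In)
At4g17600	Chl a/b binding protein	diacidic	DVD,DDDE	2	N(In)-C(In)
At4g22260	AtIM/AtPTOX	diacidic	DDD,EAE,EDDDTEEE	2	N(In)-C(In)
At4g31560	Membrane protein of unknown function	diacidic	DED,EGD	1	N(Out)-C(In)
At5g01530	AtLHCb4.1/AtCP29	diacidic	ELD,DSE,DPE	2	N(In)-C(In)
At4g18160	AtTPK3/AtKCO6	diacidic	DID,EME,DKD	5	N(Out)-C(In)
At4g01150	PsaP subunit of PSI	diacidic	EDIE	2	N(In)-C(In)
At1g06430	AtFtsH8	basic	KK	1	N(In)-C(Out)
At1g22700	AtPyg7	basic	KK	1	N(In)-C(Out)
At1g51400	PsbT subunit of PSII	basic	KK	1	N(In)-C(Out)
At4g14870	AtSECe1	dihydrophobic	FF	1	N(Out)-C(In)
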