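accession	category
At1g02910	PSII
At1g03160	thylakoid_biogenesis
At1g06430	protease_chaperone
At1g15820	LHC
At1g18730	PSI
At1g22700	PSI
At1g34000	LHC
At1g44575	PSII
At1g51400	PSII
At1g64770	PSI
At1g80030	protease_chaperone
At2g18710	transport
At2g21530	unknown
At2g26500	cytb6f
At2g28800	transport
At2g30570	PSII
At2g35490	unknown
At2g36145	unknown
At2g43560	protease_chaperone
At3g04790	stress_defense
At3g08940	LHC
At3g46780	unknown
At4g14870	transport
At4g17600	LHC
At4g18160	transport
At4g22260	thylakoid_biogenesis
At4g31560	unknown
At4g39710	PSI
At5g01530	LHC
At5g39830	protease_chaperone
At5g52970	unknown
At5g67030	stress_defense
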