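accession	name	motifs
At1g64770	AtNDF2/AtNDH45	IDALQIELSCTAGV,IVSLYPVSMATALV
At1g80030	AtDjA7	ISYLDAILGAVVKV
At2g21530	FHA-domain protein	IGRLPEKADVVIPV
At2g35490	Plastid-lipid associated protein	IPLLAAGSTPLLKV
At2g36145	Unknown protein	IDCLVFQTTENGVV
At2g43560	AtFKBP16-3	ISNLSSRREAMLLV
At3g04790	Ribose-5-phosphate isomerase	IGKLLSSGELYDIV
At3g46780	AtPTAC16	IASLVADIFANTAV
At4g39710	AtFKBP16-2	IRGLDQGILGGEGV
At5g39830	AtDeg8	ISGLNRDIFSQTGV
At5g52970	Thylakoid lumen 15.0 kDa protein	IANLEKDTGFKLRV
At5g67030	AtLOS6/AtABA1	INGLVDGISGTWYV
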