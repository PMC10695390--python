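locus_tag	gene	eop_average	sd	call_this_work	call_literature
lambdap62	ren	1.20E-02	1.7E+00	NE	NE
lambdap63	ninB	3.00E-01	9.1E-01	NE	NE
lambdap64	ninC	1.00E+00	1.5E+00	NE	NE
	ninD				NE
	ninE				NE
lambdap67	ninF	0.03	1.4E+00	NE	NE
lambdap68	ninG	0.2	2.1E-01	NE	NE
	ninH				NE
lambdap70	ninI	1	1.5E+00	NE	NE
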