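locus_tag	gene	eop_average	sd	call_this_work	call_literature
lambdap01	nu1	5.5E-06	2.1E-06	E	E
lambdap02	A	1.3E-06	4.7E-07	E	E
lambdap03	W	3.0E-05	1.4E-05	E	E
lambdap04	B	2.5E-05	2.1E-05	E	E
lambdap05	C	<2.0E-7		E	E
lambdap06	nu3	<2.0E-7		E	E
lambdap07	D	6.8E-06	2.4E-07	E	E
lambdap08	E	<6.4E-6		E	E
lambdap09	Fi	2.0E-05	0.0E+00	E	E
lambdap10	Fii	<2.0E-7		E	E
lambdap11	Z	2.5E-05	7.1E-06	E	E
lambdap12	U	3.5E-05	2.1E-05	E	E
lambdap13	V	1.7E-05	1.9E-05	E	E
lambdap14	G	<6.4E-6		E	E
lambdap15	T	1.2E-05	1.2E-05	E	E
lambdap16	H	1.0E-06	9.4E-07	E	E
lambdap17	M	<2.0E-7		E	E
lambdap18	L	<2.0E-7		E	E
lambdap19	K	8.7E-05	1.2E-04	E	E
lambdap20	I	2.6E-05	2.7E-05	E	E
lambdap21	J	1.1E-05	1.2E-05	E	E
lambdap26	lom	8.8E-01	5.3E-01	NE	NE
lambdap27	stf	3.0E+00	2.8E+00	NE	NE
lambdap90	orf206b	4.3E+00	1.1E+00	NE	NE
lambdap28	tfa	6.3E+00	5.3E+00	NE	NE
lambdap29	orf-194	3.3E+00	1.1E+00	NE	NE
lambdap80	ea47	5.5E+00	6.4E+00	NE	NE
lambdap81	ea31	1.2E+00	1.1E+00	NE	NE
lambdap82	ea59	1.3E+01	1.7E+01	NE	NE
lambdap33	int	2.8E+00	3.2E+00	NE	NE
lambdap34	xis	1.6E+00	1.1E+00	NE	NE
lambdap35				NT
lambdap36	ea8.5	1.4E+00	1.3E+00	NE	NE
lambdap83	ea22	2.2E+00	2.3E+00	NE	NE
lambdap37	orf61	9.7E-01	8.1E-01	NE	NE
lambdap38	orf63	1.3E+00	3.8E-01	NE	NE
lambdap39	orf60a	2.4E+00	2.0E+00	NE	NE
lambdap41	exo	6.9E-01	4.4E-01	NE	NE
lambdap84	bet	2.1E+00	2.5E+00	NE	NE
lambdap42	gam	1.4E+00	1.3E+00	NE	NE
lambdap85	kil	1.0E+00	0.0E+00	NE	NE
lambdap86	cIII	1.1E+00	3.1E-01	NE	NE
lambdap45	ea10	1.7E+00	4.7E-01	NE	NE
lambdap46	ral	1.1E+00	3.2E-01	NE	NE
lambdap47	orf28	1.3E+00	4.7E-01	NE	NE
lambdap48	sieB	1.5E+00	7.1E-01	NE	NE
lambdap49	N	1.8E-04	1.2E-04	E	E
lambdap53	rexB	1.4E+00	1.3E+00	NE	NE
lambdap87	rexA	3.8E+00	4.0E+00	NE	NE
lambdap88	cI	5.3E+00	6.6E+00	NE	NE
lambdap57	cro	<7.5E-6		E	E
	cII			NT	NE
lambdap89	O	<7.5E-6		E	E
lambdap61	P	<7.5E-6		E	E
lambdap62	ren	1.20E-02	7.7E-06	E	NE
lambdap63	ninB	3.00E-05	5.4E-04	E	NE
lambdap64	ninC	clearing on E-1		E	NE
	ninD			NT	NE
	ninE			NT	NE
lambdap67	ninF	4.00E-05	4.0E-06	E	NE
lambdap68	ninG	8.0E-06	1.1E-04	E	NE
	ninH			NT	NE
lambdap70	ninI	4.0E-06	5.8E-06	E	NE
lambdap71	Q	1.6E-05	6.1E-06	E	E
lambdap73	orf-64	1.2E-02	9.1E-02	NE
lambdap74	S	1.0E-05	4.6E-05	E	E
lambdap92	S'	1.0E-05	1.7E-04	E	E
lambdap75	R	6.0E-02	5.1E-02	NE	E
lambdap76	Rz	5.0E-04	1.5E-01	E	E
	Rz1			NT	E
lambdap77	bor	7.9E-01	3.0E-01	NE	NE
lambdap78	-	1.9E+00	1.3E+00	NE	NE
lambdap79	-	3.0E-04	1.1E-04	E	NE
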