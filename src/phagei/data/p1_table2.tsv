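locus_tag	gene	eop_average	sd	call_this_work	call_literature
P1_gp002	cra	6.6E-01	1.3E-01	NE	NE
P1_gp003	cre	1.2E+00	8.1E-01	NE	NE
P1_gp004	c8	1.5E+00	3.9E-01	NE
P1_gp005	ref	1.3E+00	3.5E-01	NE	NE
P1_gp006	mat	2.8E-01	3.5E-03	NE	E
P1_gp007	res	1.2E+00	3.5E-02	NE	NE
P1_gp008	mod	1.0E+00	3.2E-01	NE	NE
P1_gp009	lxc	7.0E-01	4.2E-01	NE	NE
P1_gp010	ulx	6.4E-01	1.6E-01	NE	NE
P1_gp011	darB	5.8E-01	2.5E-01	NE	NE
P1_gp012	prt	<3.4E-6		E	E
P1_gp013	pro	<3.4E-6		E	E
P1_gp115	lydE	9.8E-01	8.8E-01	NE
P1_gp014	lydD	1.1E+00	1.0E-01	NE
P1_gp015	lyz	5.0E-02	3.5E-03	E	E
P1_gp016	ssb	5.7E-01	2.0E-02	NE
P1_gp017	isaA	8.6E-01	4.7E-01	NE
P1_gp018	insB	5.1E-01	1.6E-01	NE
P1_gp019	insA	1.0E+00	2.2E-01	NE
P1_gp020	isaB	1.4E+00	2.2E-01	NE
P1_gp021	hxr	1.6E+00	1.2E+00	NE	NE
P1_gp022	ddrB	8.5E-01	1.3E-01	NE	NE
P1_gp116	iddB	5.4E-01	2.6E-01	NE	NE
P1_gp023	ddrA	9.8E-01	3.1E-01	NE	NE
P1_gp024	darA	6.5E-01	2.9E-01	NE	NE
P1_gp025	hdf	1.2E+00	8.4E-01	NE	NE
P1_gp026	lydB	2.3E-02	2.6E-02	E	NE
P1_gp027	lydA	1.2E-01	2.4E-03	NE	NE
P1_gp028	lydC	1.1E+00	1.2E-01	NE
P1_gp029	cin	1.4E+00	9.5E-01	NE	NE
P1_gp001	Sv prime	5.3E-01	3.2E-01	NE	NE
P1_gp030	U prime	8.6E-01	8.0E-01	NE	NE
P1_gp031	U	<5.2E-5		E
P1_gp032	S	<5.2E-5		E
P1_gp033	R	<5.2E-5		E	E
P1_gp034	16	<5.2E-5		E	E
P1_gp035	bplA	<2.9E-5		E
P1_gp036	pmgA	<2.9E-5		E	E
P1_gp037	sit	<2.9E-5		E
P1_gp038	pmgB	<2.9E-5		E	E
P1_gp039	tub	<2.9E-5		E
P1_gp040	pmgC	<2.9E-5		E	E
P1_gp041	simC	1.7E+00	6.9E-01	NE	NE
P1_gp042	simB	3.8E+00	8.4E-01	NE	NE
P1_gp043	simA	9.0E-01	4.9E-01	NE	NE
P1_gr044	c4 RNA	8.3E-01	9.4E-01	NE
P1_gp045	icd	6.0E-01	2.2E-01	NE	NE
P1_gp046	ant1	2.0E+00	1.1E+00	NE	NE
P1_gp047	ant2	2.3E+00	1.8E+00	NE	NE
P1_gp048	ask	1.2E+00	4.9E-01	NE
P1_gp049	kilA	8.6E-01	8.0E-01	NE	NE
P1_gp050	repL	7.1E-01	3.0E-01	NE	NE
P1_gp051	rlfA	1.3E+00	6.1E-02	NE
P1_gp052	rlfB	8.8E-01	3.0E-02	NE
P1_gp053	pmgF	1.2E+00	1.0E-02	NE	NE
P1_gp054	bplB	<1.2E-7		E
P1_gp055	pmgG	<1.2E-7		E	E
P1_gp056	21	<1.2E-7		E	*
P1_gp057	22	<1.2E-7		E	*
P1_gp058	23	<1.2E-7		E	*
P1_gp059	parB	1.3E+00	7.6E-01	NE
P1_gp060	parA	1.6E+00	1.5E+00	NE
P1_gp061	repA	9.5E-01	6.4E-02	NE
P1_gp062	upfA	1.2E+00	8.9E-01	NE	NE
P1_gp063	mlp	2.4E-01	1.9E-01	NE
P1_gp064	ppfA	1.3E+00	1.2E+00	NE
P1_gp065	upfB	1.3E+00	1.0E+00	NE	NE
P1_gp066	upfC	1.1E+00	6.8E-01	NE	NE
P1_gp067	uhr	8.6E-01	1.9E-01	NE	NE
P1_gp068	hrdC	8.7E-01	4.6E-01	NE
P1_gp069	dmt-B	1.4E+00	1.2E+00	NE	NE
P1_gp070	dmt-A	1.4E+00	7.6E-03	NE
P1_gt071	trnT	9.2E-01	4.0E-01	NE
P1_gp072	plp	1.6E+00	8.2E-01	NE
P1_gp073	upl	1.9E+00	5.9E-01	NE	NE
P1_gp074	tciA	6.5E-01	6.5E-02	NE
P1_gp075	tciB	9.9E-01	1.0E-01	NE
P1_gp076	tciC	1.3E+00	4.4E-01	NE
P1_gt117	trnI	1.4E+00	7.9E-01	NE
P1_gp077	ban	1.2E+00	4.8E-01	NE	NE
P1_gp078	dbn	1.3E+00	1.3E-01	NE	NE
P1_gp079	5	<2.1E-6		E	*
P1_gp080	6	8.3E-03	1.3E-03	E	*
P1_gp081	24	4.9E-03	5.0E-03	E	*
P1_gp082	7	<8.2E-6		E	*
P1_gp083	25	1.1E-01	6.6E-02	NE	*
P1_gp084	26	1.2E-01	1.5E-01	NE	*
P1_gp085	pmgL	1.3E+00	9.4E-01	NE	NE
P1_gp086	pmgM	3.8E-01	2.1E-01	NE	NE
P1_gp087	pmgN	1.4E-02	1.5E-03	E	NE
P1_gp088	pmgO	1.1E+00	8.7E-01	NE	NE
P1_gp089	pmgP	7.2E-01	7.3E-02	NE	NE
P1_gp090	ppp	1.2E+00	8.0E-02	NE	NE
P1_gp091	pmgQ	1.4E+00	7.5E-01	NE	NE
P1_gp092	pmgR	9.4E-01	3.0E-01	NE	E
P1_gp093	pmgS	1.2E+00	3.2E-01	NE	NE
P1_gp094	pap	7.7E-01	2.3E-01	NE	NE
P1_gp095	pmgT	9.8E-01	9.7E-01	NE	NE
P1_gp096	pmgU	2.1E-01	6.4E-02	NE	NE
P1_gp097	pmgV	1.9E+00	2.0E+00	NE	NE
P1_gp098	upfM			NT	NE
P1_gp099	upfN	8.3E-01	2.4E-01	NE	NE
P1_gp100	upfO	9.5E-01	6.4E-01	NE	NE
P1_gp101	hot	1.2E+00	1.6E+00	NE
P1_gp102	lxr	7.9E-01	7.7E-01	NE
P1_gp103	humD	5.4E-01	3.3E-01	NE
P1_gp104	phd	5.5E-01	7.1E-02	NE
P1_gp105	doc	3.6E-01	1.2E-02	NE
P1_gp106	pdcA			NT	NE
P1_gp107	pdcB	6.8E-01	2.6E-01	NE	NE
P1_gp108	lpa	<1.2E-7		E	*
P1_gp109	pacA	<1.2E-7		E	*
P1_gp110	pacB	<1.2E-7		E	*
P1_gp111	c1	1.4E+00	1.3E+00	NE
P1_gp112	coi	7.4E-01	8.4E-01	NE	NE
P1_gp113	imcB	8.2E-01	7.3E-01	NE
P1_gp114	imcA			NT
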