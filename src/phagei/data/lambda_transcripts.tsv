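unit_name	rank	locus_tag
pL	0	N
pL	1	sieB
pL	2	orf28
pL	3	ral
pL	4	ea10
pL	5	cIII
pL	6	kil
pL	7	gam
pL	8	bet
pL	9	exo
pL	10	orf60a
pL	11	orf63
pL	12	orf61
pL	13	ea22
pL	14	ea8.5
pL	15	lambdap35
pL	16	xis
pL	17	int
pL	18	ea59
pL	19	ea31
pL	20	ea47
pR	0	cro
pR	1	cII
pR	2	O
pR	3	P
pR	4	ren
pR	5	ninB
pR	6	ninC
pR	7	ninD
pR	8	ninE
pR	9	ninF
pR	10	ninG
pR	11	ninH
pR	12	ninI
pR	13	Q
pR_prime	0	orf-64
pR_prime	1	S
pR_prime	2	S'
pR_prime	3	R
pR_prime	4	Rz
pR_prime	5	Rz1
pR_prime	6	bor
pR_prime	7	lambdap78
pR_prime	8	lambdap79
pR_prime	9	nu1
pR_prime	10	A
pR_prime	11	W
pR_prime	12	B
pR_prime	13	C
pR_prime	14	nu3
pR_prime	15	D
pR_prime	16	E
pR_prime	17	Fi
pR_prime	18	Fii
pR_prime	19	Z
pR_prime	20	U
pR_prime	21	V
pR_prime	22	G
pR_prime	23	T
pR_prime	24	H
pR_prime	25	M
pR_prime	26	L
pR_prime	27	K
pR_prime	28	I
pR_prime	29	J
pR_prime	30	lom
pR_prime	31	stf
pR_prime	32	orf206b
pR_prime	33	tfa
pR_prime	34	orf-194
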