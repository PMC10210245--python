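# Cromer-Mann elastic X-ray form factor coefficients,
# f(q) = sum_i a_i exp(-b_i (q/4pi)^2) + c, valid for q <= 25 1/Angstrom.
# Source: International Tables for Crystallography Vol. C, Table 6.1.1.4.
symbol	Z	a1	a2	a3	a4	b1	b2	b3	b4	c
H	1	0.489918	0.262003	0.196767	0.049879	20.6593	7.74039	49.5519	2.20159	0.001305
C	6	2.31	1.02	1.5886	0.865	20.8439	10.2075	0.5687	51.6512	0.2156
N	7	12.2126	3.1322	2.0125	1.1663	0.0057	9.8933	28.9975	0.5826	-11.529
O	8	3.0485	2.2868	1.5463	0.867	13.2771	5.7011	0.3239	32.9089	0.2508
S	16	6.9053	5.2034	1.4379	1.5863	1.4679	22.2151	0.2536	56.172	0.8669
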