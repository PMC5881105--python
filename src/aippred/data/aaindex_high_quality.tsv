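# Eight "high-quality" AAindex scales (the cluster-central indices of the
# AAindex database clustering by Saha et al.), one column per index:
#   BLAM930101  alpha-helix propensity of position 44 in T4 lysozyme (Blaber et al., 1993)
#   BIOV880101  information value for accessibility, average fraction 35% (Biou et al., 1988)
#   MAXF760101  normalized frequency of alpha-helix (Maxfield & Scheraga, 1976)
#   TSAJ990101  residue volume from crystal packing (Tsai et al., 1999)
#   NAKH920108  AA composition of membrane proteins, single-spanning (Nakashima & Nishikawa, 1992)
#   CEDJ970104  composition of intracellular proteins (Cedano et al., 1997)
#   LIFS790101  conformational preference for all beta-strands (Lifson & Sander, 1979)
#   MIYS990104  optimized relative partition energies (Miyazawa & Jernigan, 1999)
# Each scale is min-max normalized over the 20 residues before use, so only
# the rank/spacing structure of a column matters, not its units.
residue	BLAM930101	BIOV880101	MAXF760101	TSAJ990101	NAKH920108	CEDJ970104	LIFS790101	MIYS990104
A	0.96	16	1.43	89.3	9.36	7.9	0.92	-0.04
C	0.42	168	0.94	102.5	2.56	1.9	1.16	-0.38
D	0.42	-78	0.92	114.4	0.94	5.5	0.48	0.19
E	0.53	-106	1.67	138.8	0.94	7.1	0.61	0.23
F	0.59	189	1.19	190.8	10.99	3.9	1.25	-0.38
G	0.00	-13	0.46	63.8	6.17	7.1	0.61	0.09
H	0.57	50	0.98	157.5	0.47	2.1	0.93	-0.04
I	0.84	151	1.04	163.0	13.73	5.2	1.81	-0.34
K	0.73	-141	1.27	165.1	0.58	6.7	0.70	0.33
L	0.92	145	1.36	163.1	16.64	8.6	1.30	-0.37
M	0.86	124	1.53	165.8	3.93	2.4	1.19	-0.30
N	0.39	-74	0.64	122.4	2.31	4.0	0.60	0.13
P	-2.50	-20	0.49	121.6	1.96	5.3	0.40	0.19
Q	0.80	-73	1.22	146.9	1.14	4.4	0.95	0.14
R	0.77	-70	1.18	190.3	0.27	4.9	0.93	0.07
S	0.53	-70	0.70	94.2	5.58	6.6	0.82	0.12
T	0.54	-38	0.78	119.6	4.68	5.3	1.12	0.03
V	0.63	123	0.98	138.2	12.43	6.8	1.81	-0.29
W	0.58	145	1.01	226.4	2.20	1.2	1.54	-0.33
Y	0.72	53	0.69	194.6	3.13	3.1	1.53	-0.29
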