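# Endocyclic ribose torsions (nu0..nu4), glycosidic chi and backbone gamma (degrees) for
# published (p)ppGpp conformers: two energy-minimized unbound nucleotides and four
# receptor-bound copies taken from crystal structures (PDB id given as the conformer id).
# Pseudorotation parameters (P, nu_max), pucker class and syn/anti labels are *computed*
# from these inputs by alarmone.conformation, never stored here.
id	state	nu0	nu1	nu2	nu3	nu4	chi	gamma
ppGpp_unbound	unbound	-6.88	26.92	-35.87	33.24	-16.53	-99.58	-172.55
pppGpp_unbound	unbound	-7.88	26.79	-34.64	31.48	-14.82	84.22	-177.41
6EX0	bound	-8.46	-13.71	31.52	-37.17	27.46	171.65	61.18
5VSW	bound	-13.05	25.53	-27.83	19.75	-4.28	-116.08	-177.02
6G14	bound	-22.30	33.40	-32.51	18.75	2.27	-112.79	53.43
6GFM	bound	-32.38	44.35	-38.72	19.11	8.42	65.89	-143.14
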