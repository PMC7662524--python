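start	end	p_value	q_value	sequence	loc	gene	operon_pos
81408	81423	4.03e-6	1	AGTAAACTAAAACACA	1	TTHA0081	1/3
81408	81423	4.03e-6	1	TGTGTTTTAGTTTACT	-48	TTHA0080	S
32704	32719	5.82e-6	1	TGTGTACGAAATTACA	434	TTHA0030	1/2
472203	472218	7.74e-6	1	TGTATCTTGAAAAACA	-26	TTHA0507	S
472203	472218	7.74e-6	1	TGTTTTTCAAGATACA	-56	TTHA0506	S
130005	130020	1.01e-5	1	TTTATTCTCCCTTACA	-10	TTHA0133	1/2
130005	130020	1.01e-5	1	TGTAAGGGAGAATAAA	-3	TTHA0132	S
1506	1521	1.23e-5	1	AGTGAGATAACTCACA	-666	TTHC003	1/3
1506	1521	1.23e-5	1	TGTGAGTTATCTCACT	627	TTHC002	S
79627	79642	1.30e-5	1	TGTGGTCCAGGCTACC	-78	TTHB089	1/3
79627	79642	1.30e-5	1	GGTAGCCTGGACCACA	-162	TTHB088	S
615132	615147	1.46e-5	1	GGTAGCCAGGGATACA	909	TTHA0647	4/4
1715061	1715076	1.65e-5	1	TGTAGGCCAGGCCACG	-33	TTHA1833	1/2
609145	609160	1.83e-5	1	CGTGTCCCTGAACACA	790	TTHA0641	2/4
614143	614158	2.12e-5	1	TGTGCCTTTGGCCACA	326	TTHA0645	1/3
1794923	1794938	2.33e-5	1	GGTATGCTCAAGTACA	13	TTHA1912	1/2
1794923	1794938	2.33e-5	1	TGTACTTGAGCATACC	-19	TTHA1911	1/4
1272	1287	2.61e-5	1	TGTAGCCCAGGCCAAA	239	TTHB003	S
1272	1287	2.61e-5	1	TTTGGCCTGGGCTACA	536	TTHB004	4/4
199120	199135	2.90e-5	1	TGTGGCGTATAACAAA	-17	TTHA0202	S
199120	199135	2.90e-5	1	TTTGTTATACGCCACA	-103	TTHA0201	S
357035	357050	3.43e-5	1	AGTGATGTAAACTAAA	-26	TTHA0374	S
314103	314118	3.67e-5	1	TGTGTTGCAGGACCCA	58	TTHA0326	2/11
1540358	1540373	3.95e-5	1	TGTAGCTTCCCATACC	-67	TTHA1627	S
1540358	1540373	3.95e-5	1	GGTATGGGAAGCTACA	13	TTHA1626	S
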