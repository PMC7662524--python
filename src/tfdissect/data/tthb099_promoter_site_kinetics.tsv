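gene	sequence	kon	koff	kd	r_squared
TTHA0080/81	TGTGTTTTAGTTTACT	122852	1.145e-2	9.322e-8	0.9817
TTHA0506/07	TGTTTTTCAAGATACA	164971	1.280e-2	7.762e-8	0.9718
TTHA0132/33	TGTAAGGGAGAATAAA	96736	2.140e-2	2.212e-7	0.9687
TTHB088/89	GGTAGCCTGGACCACA	214153	7.163e-4	3.345e-9	0.9805
TTHA1833	TGTAGGCCAGGCCACG	332611	1.013e-3	3.046e-9	0.9757
TTHA1911/12	TGTACTTGAGCATACC	136294	8.938e-3	6.558e-8	0.9806
TTHA0201/02	TTTGTTATACGCCACA	57231	4.464e-2	7.801e-7	0.9596
TTHA0374	AGTGATGTAAACTAAA
TTHA1626/27	GGTATGGGAAGCTACA	126605	1.291e-2	1.020e-7	0.9759
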