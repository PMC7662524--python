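name	sequence	kon	koff	kd	r_squared
wt	TGTATTCTAGAATACA	131308	2.907e-4	2.214e-9	0.9883
m1	gGTATTCTAGAATACA	120059	7.558e-4	6.295e-9	0.9895
m2	TtTATTCTAGAATACA	112773	3.785e-3	3.356e-8	0.9778
m3	TGaATTCTAGAATACA	88146	1.221e-3	1.385e-8	0.9824
m4	TGTcTTCTAGAATACA	142953	1.366e-3	9.557e-9	0.9817
m5	TGTAcTCTAGAATACA	110766	5.379e-4	4.856e-9	0.9879
m6	TGTATaCTAGAATACA	125945	7.064e-4	5.608e-9	0.9794
m7	TGTATTtTAGAATACA	119827	6.978e-4	5.823e-9	0.9805
m8	TGTATTCaAGAATACA	115299	7.848e-4	6.807e-9	0.9840
wt+cAMP	TGTATTCTAGAATACA	214759	4.780e-4	2.226e-9	0.9231
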