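subtype	rank	gene	p_value	q_value
Basal-like	1	MLPH	4.0e-41	8.2e-37
Basal-like	2	FOXA1	9.6e-40	6.6e-36
Basal-like	3	FOXC1	1.0e-38	3.4e-35
Basal-like	4	ESR1	1.0e-35	6.5e-33
Basal-like	5	NAT1	1.4e-35	8.1e-33
Her2E	1	FGFR4	4.6e-19	4.3e-15
Her2E	2	GRB7	5.6e-16	7.7e-13
Her2E	3	ERBB2	1.4e-15	1.6e-12
Her2E	4	BCL2	5.2e-14	2.8e-11
Her2E	5	ESR1	3.6e-12	9.5e-10
LumA	1	CEP55	2.4e-50	1.2e-46
LumA	2	MYBL2	7.0e-49	2.4e-45
LumA	3	MELK	3.8e-47	5.2e-44
LumA	4	KIF2C	7.5e-47	9.6e-44
LumA	5	ANLN	1.2e-46	1.5e-43
LumB	1	KRT17	2.0e-20	6.8e-17
LumB	2	SFRP1	7.7e-20	1.6e-16
LumB	3	KRT14	5.7e-18	4.3e-15
LumB	4	KRT5	1.6e-17	8.7e-15
LumB	5	EGFR	1.1e-16	5.0e-14
Normal-like	1	ERBB2	5.4e-3	2.4e-1
Normal-like	2	KRT14	2.3e-3	2.4e-1
Normal-like	3	KRT5	3.0e-3	2.4e-1
Normal-like	4	MIA	3.2e-3	2.4e-1
Normal-like	5	SFRP1	4.9e-3	2.5e-1
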