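# Published top-probe case-control methylation signature at the CCDC163P-MMACHC (CpG:33) and TESK2 (CpG:51) promoter CpG islands; epi-cblC phenotype, 17 cases vs 350 controls; GRCh37 positions
probe_id	chromosome	position	island_id	island_relation	locus	p_nominal	p_bonferroni	beta_cases	beta_controls	delta_beta
cg12630522	1	45956424	CpG:51	in_island	TESK2 promoter	3.86e-223	1.74e-217	0.55	0.01	0.54
cg19250177	1	45956646	CpG:51	in_island	TESK2 promoter	7.56e-204	3.42e-198	0.46	0.01	0.45
cg25827112	1	45956773	CpG:51	in_island	TESK2 promoter	4.96e-192	2.25e-186	0.46	0.06	0.41
cg27633763	1	45956828	CpG:51	in_island	TESK2 promoter	1.22e-94	5.53e-89	0.49	0.03	0.47
cg19551082	1	45956882	CpG:51	in_island	TESK2 promoter	3.62e-148	1.64e-142	0.32	0.06	0.27
cg00103132	1	45956932	CpG:51	flank	TESK2 upstream 5' end	4.42e-212	2.00e-206	0.42	0.04	0.38
cg00609097	1	45956974	CpG:51	flank	TESK2 upstream 5' end	6.61e-195	2.99e-189	0.48	0.05	0.43
cg24296786	1	45957014	CpG:51	flank	TESK2 upstream 5' end	2.75e-199	1.24e-193	0.53	0.05	0.48
cg04132845	1	45957038	CpG:51	flank	TESK2 upstream 5' end	1.96e-218	8.85e-213	0.46	0.06	0.41
cg15605315	1	45957053	CpG:51	flank	TESK2 upstream 5' end	3.07e-196	1.39e-190	0.50	0.03	0.46
cg05765466	1	45957060	CpG:51	flank	TESK2 upstream 5' end	8.34e-203	3.77e-197	0.46	0.08	0.38
cg13848568	1	45965625	CpG:33	in_island	CCDC163P-MMACHC bidirectional promoter	1.87e-138	8.44e-133	0.39	0.04	0.35
cg00081251	1	45965679	CpG:33	in_island	CCDC163P-MMACHC bidirectional promoter	2.89e-182	1.31e-176	0.52	0.07	0.45
cg09323228	1	45965727	CpG:33	in_island	CCDC163P-MMACHC bidirectional promoter	1.18e-171	5.33e-166	0.49	0.05	0.44
cg27393325	1	45965846	CpG:33	in_island	CCDC163P-MMACHC bidirectional promoter	2.16e-195	9.79e-190	0.52	0.02	0.50
cg22536808	1	45965870	CpG:33	in_island	CCDC163P-MMACHC bidirectional promoter	7.73e-167	3.50e-161	0.42	0.00	0.42
cg14836864	1	45965990	CpG:33	in_island	CCDC163P-MMACHC bidirectional promoter	2.33e-167	1.05e-161	0.43	0.03	0.40
cg03108114	1	45966048	CpG:33	in_island	CCDC163P-MMACHC bidirectional promoter	1.51e-208	6.82e-203	0.54	0.02	0.51
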