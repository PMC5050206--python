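trait_id	gene_id	eqtl_type	chrom	start	end	max_lr	fdr
T_G01	G01	total-expression	chr1	10000000	12000000	45.1	0.0
T_G02_iso	G02	isoform-ratio	chr1	20000000	22000000	38.2	0.002
T_G02	G02	total-expression	chr2	5000000	7000000	41.7	0.0
T_G04	G04	total-expression	chr1	30000000	32000000	36.9	0.004
T_G05	G05	total-expression	chr3	0	2000000	52.3	0.0
T_G06	G06	total-expression	chr4	40000000	42000000	33.5	0.008
T_G07	G07	total-expression	chr3	12000000	14000000	40.0	0.0
T_G08	G08	isoform-ratio	chr3	15000000	17000000	35.2	0.005
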