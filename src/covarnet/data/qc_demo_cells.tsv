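cell	total_reads	frac_mapped	frac_genes_detected	frac_spikein	frac_mito	frac_pcr_dup
c01	250000	0.85	0.45	0.005	0.02	0.20
c02	150000	0.95	0.60	0.001	0.01	0.10
c03	250000	0.85	0.45	0.02	0.06	0.35
c04	300000	0.90	0.50	0.009	0.049	0.29
c05	250000	0.80	0.45	0.005	0.02	0.20
c06	250000	0.85	0.40	0.005	0.02	0.20
c07	201000	0.81	0.41	0.0	0.0	0.0
c08	200000	0.85	0.45	0.005	0.02	0.20
c09	500000	0.95	0.55	0.001	0.01	0.05
c10	250000	0.85	0.45	0.005		0.20
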