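ligand	K_I_M	K_I_sd_M	substrate	kcat_over_KM	kcat_over_KM_sd	provenance
SPhe	3.51e-5	4.22e-6	ZAAF	2.0e5		cited
SLeu	8.94e-6	1.23e-6	ZAAL	2.2e5	5.88e4	measured
SArg	3.4e-4	8.8e-6	ZAAR	1.95e4	4.5e3	measured
SGlu	3.09e-3	5.56e-4	ZAAE	3.17e3	1.84e3	measured
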